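"""Shared fixtures: small synthetic inputs generated at test time."""

import textwrap

import pandas as pd
import pytest

# Hand-written synthetic UniProtKB-style records (fictional accessions and
# sequences) exercising glycosylation, modified-residue, lipidation, motif,
# domain and excluded (DISULFID) feature classes plus an isoform accession.
SYNTHETIC_UNIPROT = """\
ID   SYN1_HUMAN              Reviewed;         180 AA.
AC   P99901; P99901-2;
DT   01-JAN-2020, integrated into UniProtKB/Swiss-Prot.
DE   RecName: Full=Synthetic test protein 1;
OS   Homo sapiens (Human).
OC   Eukaryota.
FT   CARBOHYD        45
FT                   /note="N-linked (GlcNAc...) asparagine"
FT   CARBOHYD        54
FT                   /note="N-linked (GlcNAc...) asparagine"
FT   MOD_RES         10
FT                   /note="Phosphoserine; by CK2"
FT   MOTIF           100..103
FT                   /note="PTAP motif"
FT   DOMAIN          20..90
FT                   /note="PSI"
SQ   SEQUENCE   180 AA;  19000 MW;  0123456789ABCDEF CRC64;
     MKTAYIAKQR QISFVKSHFS RQLEERLGLI EVQAPILSRV GDGTQDNLSG AEKAVQVKVK
//
ID   SYN2_HUMAN              Reviewed;         250 AA.
AC   P99902;
DT   01-JAN-2020, integrated into UniProtKB/Swiss-Prot.
DE   RecName: Full=Synthetic test protein 2;
OS   Homo sapiens (Human).
OC   Eukaryota.
FT   CARBOHYD        12
FT                   /note="O-linked (GalNAc...) serine"
FT   LIPID           2
FT                   /note="N-myristoyl glycine"
FT   DISULFID        30..60
FT                   /note="Interchain"
FT   DOMAIN          110..200
FT                   /note="SPRY"
SQ   SEQUENCE   250 AA;  27000 MW;  FEDCBA9876543210 CRC64;
     MGSSKSKPKD PSQRRRSLEP AENVHGAGGG AFPASQTPSK PASADGHRGP SAAFAPAAAE
//
"""


@pytest.fixture
def uniprot_text():
    return SYNTHETIC_UNIPROT


@pytest.fixture
def simple_tsv_text():
    return textwrap.dedent(
        """\
        protein_id\tcategory\tname\tsite
        P1\tPTM\tN-linked (GlcNAc...) asparagine\t45
        P1\tPTM\tN-linked (GlcNAc...) asparagine\t54
        P2\tPTM\tO-linked (GalNAc...) serine\t12
        P2\tPTM\tN-myristoyl glycine\t2
        P3\tMOTIF\tPTAP motif\t100..103
        P3\tDOMAIN\tPSI\t20..90
        """
    )


def make_toy_abundance(tmp_path, areas, samples):
    """Write an abundance TSV + metadata TSV and return both paths.

    ``areas``: dict protein_id -> list of values (may contain None for
    blanks); ``samples``: list of (sample_id, dataset, compartment,
    replicate) tuples.
    """
    sample_ids = [s[0] for s in samples]
    table = tmp_path / "abundance.tsv"
    with open(table, "w") as fh:
        fh.write("protein_id\t" + "\t".join(sample_ids) + "\n")
        for pid, vals in areas.items():
            cells = ["" if v is None else str(v) for v in vals]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")
    meta = tmp_path / "samples.tsv"
    pd.DataFrame(
        samples, columns=["sample_id", "dataset", "compartment", "replicate"]
    ).to_csv(meta, sep="\t", index=False)
    return table, meta


@pytest.fixture
def toy_abundance(tmp_path):
    samples = [
        ("S_EV_1", "DS1", "EV", 1),
        ("S_EV_2", "DS1", "EV", 2),
        ("S_CELL_1", "DS1", "CELL", 1),
    ]
    areas = {
        "P1": [10, 30, 4],
        "P2": [999, 999, 99],
        "P3": [0, None, 0],
    }
    return make_toy_abundance(tmp_path, areas, samples)
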