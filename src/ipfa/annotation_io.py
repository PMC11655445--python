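"""Parse, deduplicate, pool and filter protein feature annotations.

Feature annotations (post-translational modifications, short motifs,
domains) are read either from UniProtKB flat text (``FT`` feature lines,
via Biopython's SwissProt parser) or from a simplified four-column TSV
dialect.  Each feature — a (category, name) pair such as
``("PTM", "N-linked (GlcNAc...) asparagine")`` — maps to the set of
proteins that carry it; these carrier sets are the groups tested for
enrichment downstream.

Related modifications can additionally be pooled (e.g. all glycosylation
classes into one "glycosylation" feature) so that a broad modification
family is tested alongside its individual members.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from Bio import SwissProt

from .errors import ConfigurationError, ParseError, ValidationError

__all__ = [
    "FeatureAnnotation",
    "FeatureCatalog",
    "PoolRule",
    "DEFAULT_FEATURE_CLASSES",
    "DEFAULT_POOLING_MAP",
    "parse_feature_annotations",
    "pool_features",
    "filter_by_group_size",
    "load_pooling_map",
    "load_synonyms",
]

CATEGORIES = ("PTM", "MOTIF", "DOMAIN", "POOLED")

#: UniProt feature-table class -> ipfa category.  Glycosylation sites,
#: modified residues and lipidation sites count as PTMs; cross-links and
#: disulfide bonds are deliberately absent from the default set (they
#: describe covalent topology rather than reversible decoration) but any
#: FT class may be opted in through the ``classes`` argument.
DEFAULT_FEATURE_CLASSES: dict[str, str] = {
    "CARBOHYD": "PTM",
    "MOD_RES": "PTM",
    "LIPID": "PTM",
    "MOTIF": "MOTIF",
    "DOMAIN": "DOMAIN",
}

_ISOFORM_SUFFIX = re.compile(r"-\d+$")
_WS = re.compile(r"\s+")


def _normalise_name(name: str) -> str:
    """Trim, collapse whitespace and drop qualifier text after ';'.

    UniProt notes often append provenance qualifiers
    ("Phosphoserine; by CK2"); the text before the first semicolon is the
    feature identity.  Matching is case-sensitive.
    """
    name = name.split(";", 1)[0]
    return _WS.sub(" ", name).strip()


def _collapse_isoform(accession: str) -> str:
    return _ISOFORM_SUFFIX.sub("", accession.strip())


@dataclass(frozen=True, order=True)
class FeatureAnnotation:
    """One feature occurrence on one protein.

    ``site`` is a 1-based inclusive residue range (``(45, 45)`` for a
    single residue) or ``None`` when the source gives no location.
    ``source_class`` keeps the originating UniProt FT class (``CARBOHYD``,
    ``MOD_RES``, ...) when known; pooling rules may select on it.
    """

    protein_id: str
    category: str
    name: str
    site: tuple[int, int] | None = None
    source_class: str | None = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("FeatureAnnotation.protein_id must be non-empty")
        if not self.name:
            raise ValidationError("FeatureAnnotation.name must be non-empty")
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.site is not None:
            start, end = self.site
            if start < 1 or end < start:
                raise ValidationError(f"invalid site range {self.site!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.category, self.name)


class FeatureCatalog:
    """Deduplicated feature annotations plus derived carrier sets.

    Carrier membership is per protein: a protein bearing a feature at
    three sites contributes once to that feature's carrier set.
    ``detected_counts`` is populated by :func:`filter_by_group_size` and
    holds the number of detected carriers per retained feature (the "n"
    reported alongside each feature in result tables).
    """

    def __init__(
        self,
        annotations: Iterable[FeatureAnnotation],
        provenance: str = "",
        pooled_family: Mapping[str, str] | None = None,
        detected_counts: Mapping[tuple[str, str], int] | None = None,
    ):
        # exact-tuple dedup; sorted for deterministic iteration
        self.annotations: tuple[FeatureAnnotation, ...] = tuple(
            sorted(set(annotations))
        )
        self.provenance = provenance
        self.pooled_family: dict[str, str] = dict(pooled_family or {})
        self.detected_counts: dict[tuple[str, str], int] | None = (
            dict(detected_counts) if detected_counts is not None else None
        )
        carriers: dict[tuple[str, str], set[str]] = {}
        for ann in self.annotations:
            carriers.setdefault(ann.key, set()).add(ann.protein_id)
        self.carriers: dict[tuple[str, str], frozenset[str]] = {
            k: frozenset(v) for k, v in carriers.items()
        }

    @property
    def features(self) -> set[tuple[str, str]]:
        return set(self.carriers)

    def carriers_of(self, key: tuple[str, str]) -> frozenset[str]:
        return self.carriers[key]

    def family(self, key: tuple[str, str]) -> str:
        """Category family used to group multiple-testing corrections.

        Pooled features inherit the category of their members (a pool of
        glycosylation PTMs is corrected within the PTM family).
        """
        category, name = key
        if category == "POOLED":
            return self.pooled_family.get(name, "PTM")
        return category

    def __len__(self) -> int:
        return len(self.carriers)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureCatalog):
            return NotImplemented
        return self.annotations == other.annotations

    def __repr__(self) -> str:
        return (
            f"FeatureCatalog({len(self.carriers)} features, "
            f"{len(self.annotations)} annotations)"
        )

    # ---- serialization ------------------------------------------------

    def write_annotations_tsv(self, path: str | Path) -> None:
        """Write the annotation-level simplified TSV dialect.

        Parsing this file back reproduces the catalog exactly (the
        round-trip drops only ``source_class``, which the dialect does
        not carry).
        """
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("protein_id\tcategory\tname\tsite\n")
            for ann in self.annotations:
                site = ""
                if ann.site is not None:
                    start, end = ann.site
                    site = str(start) if start == end else f"{start}..{end}"
                fh.write(f"{ann.protein_id}\t{ann.category}\t{ann.name}\t{site}\n")

    def write_summary_tsv(self, path: str | Path) -> None:
        """Write one row per feature: key, carrier count, carriers."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("category\tname\tn_carriers\tcarriers\n")
            for key in sorted(self.carriers):
                cat, name = key
                carr = sorted(self.carriers[key])
                fh.write(f"{cat}\t{name}\t{len(carr)}\t{','.join(carr)}\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "provenance": self.provenance,
            "features": [
                {
                    "category": cat,
                    "name": name,
                    "n_carriers": len(self.carriers[(cat, name)]),
                    "carriers": sorted(self.carriers[(cat, name)]),
                }
                for cat, name in sorted(self.carriers)
            ],
        }
        if self.detected_counts is not None:
            payload["detected_counts"] = {
                f"{cat}\t{name}": n
                for (cat, name), n in sorted(self.detected_counts.items())
            }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


@dataclass(frozen=True)
class PoolRule:
    """Membership rule for one pooled feature.

    A raw feature joins the pool if its category matches and any of the
    three selectors hits: its UniProt source class is in ``classes``, its
    name is in ``names``, or its name matches ``pattern`` (regex search).
    """

    category: str = "PTM"
    classes: frozenset[str] = frozenset()
    names: frozenset[str] = frozenset()
    pattern: str | None = None

    def matches(self, ann: FeatureAnnotation) -> bool:
        if ann.category != self.category:
            return False
        if ann.source_class is not None and ann.source_class in self.classes:
            return True
        if ann.name in self.names:
            return True
        if self.pattern is not None and re.search(self.pattern, ann.name):
            return True
        return False


#: Pools shipped by default: whole-family features for glycosylation and
#: lipidation, matched by UniProt FT class.
DEFAULT_POOLING_MAP: dict[str, PoolRule] = {
    "glycosylation": PoolRule(category="PTM", classes=frozenset({"CARBOHYD"})),
    "lipidation": PoolRule(category="PTM", classes=frozenset({"LIPID"})),
}


def load_pooling_map(path: str | Path) -> dict[str, PoolRule]:
    """Read a pooling map from YAML.

    Format: ``pooled_name: {category: PTM, classes: [...], names: [...],
    pattern: ...}``; all selector keys optional.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"pooling map {path} must be a mapping")
    out: dict[str, PoolRule] = {}
    for name, spec in raw.items():
        spec = spec or {}
        out[str(name)] = PoolRule(
            category=spec.get("category", "PTM"),
            classes=frozenset(spec.get("classes", ())),
            names=frozenset(spec.get("names", ())),
            pattern=spec.get("pattern"),
        )
    return out


def load_synonyms(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (variant name -> canonical name)."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"synonym file needs 2 columns, got {len(parts)}", i)
        out[parts[0].strip()] = parts[1].strip()
    return out


# ---------------------------------------------------------------------------
# parsing


def parse_feature_annotations(
    source: str | Path | TextIO,
    classes: Mapping[str, str] | Iterable[str] | None = None,
    dialect: str = "auto",
    synonyms: Mapping[str, str] | None = None,
) -> FeatureCatalog:
    """Parse feature annotations into a :class:`FeatureCatalog`.

    Parameters
    ----------
    source
        Path or open text handle; UniProt flat text or the simplified
        TSV dialect (header ``protein_id  category  name  site``).
    classes
        UniProt FT classes to extract, either a mapping class -> category
        or an iterable of class keys looked up in
        :data:`DEFAULT_FEATURE_CLASSES`.  Ignored for the TSV dialect,
        which states categories explicitly.
    dialect
        ``"uniprot"``, ``"tsv"`` or ``"auto"`` (sniff from content).
    synonyms
        Optional name-merge table applied after normalisation; stands in
        for manual curation of equivalent feature labels.
    """
    if classes is None:
        class_map = dict(DEFAULT_FEATURE_CLASSES)
    elif isinstance(classes, Mapping):
        class_map = dict(classes)
    else:
        class_map = {}
        for cls in classes:
            if cls not in DEFAULT_FEATURE_CLASSES:
                raise ConfigurationError(
                    f"feature class {cls!r} has no default category; pass a "
                    "class->category mapping to include it"
                )
            class_map[cls] = DEFAULT_FEATURE_CLASSES[cls]
    if not class_map:
        raise ConfigurationError("feature class set must be non-empty")
    for cls, cat in class_map.items():
        if cat not in ("PTM", "MOTIF", "DOMAIN"):
            raise ConfigurationError(f"class {cls!r} maps to unknown category {cat!r}")

    if hasattr(source, "read"):
        text = source.read()
        origin = "<stream>"
    else:
        text = Path(source).read_text(encoding="utf-8")
        origin = str(source)

    if dialect == "auto":
        stripped = text.lstrip()
        if stripped.startswith("ID ") or stripped.startswith("AC "):
            dialect = "uniprot"
        elif not stripped or stripped.startswith("protein_id"):
            dialect = "tsv"
        else:
            raise ConfigurationError(
                f"cannot sniff annotation dialect of {origin}; pass dialect="
            )
    if dialect == "uniprot":
        anns = _parse_uniprot(text, class_map)
    elif dialect == "tsv":
        anns = _parse_simple_tsv(text)
    else:
        raise ConfigurationError(f"unknown annotation dialect {dialect!r}")

    if synonyms:
        anns = [
            replace(a, name=synonyms.get(a.name, a.name)) for a in anns
        ]
    return FeatureCatalog(anns, provenance=f"{dialect}:{origin}")


def _parse_uniprot(text: str, class_map: Mapping[str, str]) -> list[FeatureAnnotation]:
    anns: list[FeatureAnnotation] = []
    try:
        records = list(SwissProt.parse(io.StringIO(text)))
    except ValueError as exc:
        raise ParseError(f"malformed UniProt flat text: {exc}") from exc
    for rec in records:
        if not rec.accessions:
            raise ParseError(f"record {rec.entry_name!r} has no accession")
        accession = _collapse_isoform(rec.accessions[0])
        for feat in rec.features:
            if feat.type not in class_map:
                continue
            name = _normalise_name(str(feat.qualifiers.get("note", "")) or feat.type)
            try:
                start = int(feat.location.start) + 1  # biopython is 0-based
                end = int(feat.location.end)
                site = (start, end)
            except (TypeError, ValueError):
                site = None  # unknown/uncertain endpoints (e.g. '?', '<1')
            anns.append(
                FeatureAnnotation(
                    protein_id=accession,
                    category=class_map[feat.type],
                    name=name,
                    site=site,
                    source_class=feat.type,
                )
            )
    return anns


def _parse_simple_tsv(text: str) -> list[FeatureAnnotation]:
    lines = text.splitlines()
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    expected = ["protein_id", "category", "name", "site"]
    if [h.strip() for h in header] != expected:
        raise ParseError(
            f"expected header {expected}, got {header}", line_number=1
        )
    anns: list[FeatureAnnotation] = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(f"expected 4 columns, got {len(parts)}", i)
        pid, category, name, site_txt = (p.strip() for p in parts)
        site: tuple[int, int] | None = None
        if site_txt:
            m = re.fullmatch(r"(\d+)(?:(?:\.\.|-)(\d+))?", site_txt)
            if not m:
                raise ParseError(f"unparseable site {site_txt!r}", i)
            start = int(m.group(1))
            end = int(m.group(2)) if m.group(2) else start
            site = (start, end)
        try:
            anns.append(
                FeatureAnnotation(
                    protein_id=_collapse_isoform(pid),
                    category=category,
                    name=_normalise_name(name),
                    site=site,
                )
            )
        except ValidationError as exc:
            raise ParseError(str(exc), i) from exc
    return anns


# ---------------------------------------------------------------------------
# pooling and filtering


def pool_features(
    catalog: FeatureCatalog, pooling: Mapping[str, PoolRule]
) -> FeatureCatalog:
    """Add one POOLED feature per rule; raw features are untouched.

    The pooled carrier set is the union of the carrier sets of matching
    member features.  Rules matching no annotation add nothing.  A pooled
    name colliding with an existing raw name in its member category is a
    configuration error.
    """
    new_anns = list(catalog.annotations)
    pooled_family = dict(catalog.pooled_family)
    for pooled_name, rule in pooling.items():
        if (rule.category, pooled_name) in catalog.carriers:
            raise ConfigurationError(
                f"pooled name {pooled_name!r} collides with an existing "
                f"{rule.category} feature"
            )
        members = [a for a in catalog.annotations if rule.matches(a)]
        if not members:
            continue
        pooled_family[pooled_name] = rule.category
        for pid in {a.protein_id for a in members}:
            new_anns.append(
                FeatureAnnotation(protein_id=pid, category="POOLED", name=pooled_name)
            )
    return FeatureCatalog(
        new_anns,
        provenance=catalog.provenance,
        pooled_family=pooled_family,
        detected_counts=catalog.detected_counts,
    )


def filter_by_group_size(
    catalog: FeatureCatalog, detected: Iterable[str], min_n: int = 5
) -> FeatureCatalog:
    """Keep features carried by at least ``min_n`` detected proteins.

    Carrier sets are first intersected with ``detected`` (the proteins
    present in the abundance dataset under analysis); features whose
    detected-carrier count falls below ``min_n`` are dropped for lack of
    statistical power.  The surviving counts are recorded on the result.
    """
    if min_n < 1:
        raise ConfigurationError(f"min_n must be >= 1, got {min_n}")
    detected_set = set(detected)
    counts: dict[tuple[str, str], int] = {}
    for key, carr in catalog.carriers.items():
        n = len(carr & detected_set)
        if n >= min_n:
            counts[key] = n
    kept = [
        a
        for a in catalog.annotations
        if a.key in counts and a.protein_id in detected_set
    ]
    return FeatureCatalog(
        kept,
        provenance=catalog.provenance,
        pooled_family=catalog.pooled_family,
        detected_counts=counts,
    )
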