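"""Cross-dataset intersection of enriched features and candidate ranking.

Features called EV-enriched in each producer cell line are decomposed
into exact Venn regions (which subset of datasets each feature is
enriched in); features enriched in every dataset are the robust,
cell-line-independent candidates.  For a chosen feature the carrier
proteins detected in the data are then ranked by sequence length,
shortest first — the rationale being that a small EV-enriched carrier is
the easiest scaffold to engineer fusions onto.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .annotation_io import FeatureCatalog
from .errors import IPFAError, ValidationError

__all__ = ["VennSummary", "CandidateRanking", "intersect_enriched", "rank_scaffold_candidates"]

logger = logging.getLogger(__name__)

FeatureKey = tuple[str, str]


@dataclass
class VennSummary:
    """Exact region decomposition of enriched-feature sets.

    ``region_features`` maps each non-empty subset of dataset names
    (frozenset) to the features enriched in exactly those datasets;
    regions are disjoint by construction and their counts sum to the
    size of the union of all enriched sets.  ``config_hash`` ties the
    summary to the enrichment configuration that produced its inputs so
    summaries from different configurations are never mixed.
    """

    dataset_names: tuple[str, ...]
    region_features: dict[frozenset, set]
    config_hash: str | None = None

    @property
    def region_counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.region_features.items()}

    @property
    def common(self) -> set:
        return set(self.region_features.get(frozenset(self.dataset_names), set()))

    def _region_label(self, region: frozenset) -> str:
        return "+".join(sorted(region))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "datasets": list(self.dataset_names),
            "config_hash": self.config_hash,
            "regions": [
                {
                    "datasets": sorted(region),
                    "count": len(feats),
                    "features": sorted("\t".join(f) for f in feats),
                }
                for region, feats in sorted(
                    self.region_features.items(),
                    key=lambda kv: (len(kv[0]), sorted(kv[0])),
                )
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for region, feats in sorted(
            self.region_features.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
        ):
            for feat in sorted(feats):
                cat, name = feat
                rows.append((self._region_label(region), cat, name))
        df = pd.DataFrame(rows, columns=["region", "category", "name"])
        df.to_csv(path, sep="\t", index=False)


def intersect_enriched(
    per_dataset: Mapping[str, Iterable[FeatureKey]],
    config_hash: str | None = None,
) -> VennSummary:
    """Partition enriched features by the exact datasets they appear in."""
    if len(per_dataset) < 2:
        raise ValidationError(
            f"need >= 2 datasets to intersect, got {len(per_dataset)}"
        )
    sets = {ds: set(feats) for ds, feats in per_dataset.items()}
    names = tuple(sets)
    regions: dict[frozenset, set] = {}
    for feat in set().union(*sets.values()):
        member_of = frozenset(ds for ds, s in sets.items() if feat in s)
        regions.setdefault(member_of, set()).add(feat)
    return VennSummary(
        dataset_names=names, region_features=regions, config_hash=config_hash
    )


@dataclass
class CandidateRanking:
    """Detected carriers of one feature, smallest protein first.

    ``ranked`` has columns protein_id, length_aa, log10_ratio, sorted
    ascending by length with ties broken lexicographically by accession.
    """

    feature: FeatureKey
    ranked: pd.DataFrame
    tie_rule: str = "ascending length, then lexicographic accession"

    def to_tsv(self, path: str | Path) -> None:
        out = self.ranked.copy()
        out.insert(0, "name", self.feature[1])
        out.insert(0, "category", self.feature[0])
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def rank_scaffold_candidates(
    feature: FeatureKey,
    catalog: FeatureCatalog,
    lengths: Mapping[str, int],
    ratios: pd.Series,
) -> CandidateRanking:
    """Rank a feature's detected carriers by sequence length (ascending).

    Carriers absent from ``ratios`` (not detected in the dataset) are
    excluded; carriers with no known length are excluded with a warning.
    The smallest carrier heads the list — the minimal-engineering
    scaffold candidate for that feature.
    """
    if feature not in catalog.carriers:
        raise IPFAError(f"feature {feature!r} not present in catalog")
    detected = catalog.carriers_of(feature) & set(ratios.index)
    rows = []
    for pid in sorted(detected):
        if pid not in lengths:
            logger.warning("no length for carrier %s; excluded from ranking", pid)
            continue
        rows.append((pid, int(lengths[pid]), float(ratios.loc[pid])))
    df = pd.DataFrame(rows, columns=["protein_id", "length_aa", "log10_ratio"])
    df = df.sort_values(["length_aa", "protein_id"], kind="mergesort").reset_index(
        drop=True
    )
    return CandidateRanking(feature=feature, ranked=df)
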