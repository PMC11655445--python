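"""Feature-enrichment testing of EV:cell log-ratio distributions.

For each feature, the log10 EV:cell ratios of its carrier proteins are
compared with the all-protein background by the two-sample
Kolmogorov-Smirnov test.  P-values are corrected with the
Benjamini-Yekutieli step-up procedure (valid under arbitrary dependence
between features, which share carrier proteins), and a feature is called
EV-enriched when it is significant AND its carrier median ratio exceeds
the background median — the KS test itself is two-sided, so direction is
enforced by the median criterion alone.

The KS statistic D is computed with an integer numerator: for samples of
sizes n and m every ECDF difference is a multiple of 1/(n*m), so
D = D_num/(n*m) with D_num an exact integer.  The small-sample p-value
is evaluated *conditionally on the observed pooled values* (ties and
all) by dynamic programming over group/background assignments — it
therefore agrees exactly with full permutation enumeration, and with the
classical distribution-free null when there are no ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .annotation_io import FeatureCatalog
from .errors import ConfigurationError, ValidationError

__all__ = [
    "EnrichmentConfig",
    "ks_two_sample",
    "adjust_benjamini_yekutieli",
    "classify_enrichment",
    "run_enrichment",
    "RESULT_COLUMNS",
    "write_results",
]

#: Fixed column order of enrichment result tables.
RESULT_COLUMNS = [
    "category",
    "name",
    "n_carriers",
    "D",
    "p_raw",
    "p_adj",
    "median_group",
    "median_all",
    "enriched",
]

#: Largest min(n, m) for which the exact conditional null is used by
#: default; beyond this the asymptotic Kolmogorov distribution is an
#: excellent and much cheaper approximation.
EXACT_N_LIMIT = 25


@dataclass(frozen=True)
class EnrichmentConfig:
    """Knobs of the enrichment call.

    alpha
        Significance threshold on the (by default BY-adjusted) p-value.
    min_group_size
        Minimum detected carriers for a feature to be tested.
    apply_adjustment_to_threshold
        Compare alpha against p_adj (default) rather than p_raw.
    background_mode
        ``all_including_carriers`` (default; the background violin is
        "all proteins") or ``all_excluding_carriers`` for sensitivity
        analysis.
    p_method
        ``auto`` (exact below EXACT_N_LIMIT, else asymptotic),
        ``exact_small_n``, ``asymptotic`` or ``permutation``.
    by_family_mode
        ``per_category``: BY correction runs separately within the PTM,
        MOTIF and DOMAIN families (pools join their member family);
        ``joint``: one correction across all features.
    """

    alpha: float = 0.05
    min_group_size: int = 5
    apply_adjustment_to_threshold: bool = True
    background_mode: str = "all_including_carriers"
    p_method: str = "auto"
    by_family_mode: str = "per_category"
    permutation_rounds: int = 10_000
    permutation_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_group_size < 1:
            raise ConfigurationError("min_group_size must be >= 1")
        if self.background_mode not in (
            "all_including_carriers",
            "all_excluding_carriers",
        ):
            raise ConfigurationError(f"unknown background_mode {self.background_mode!r}")
        if self.p_method not in ("auto", "exact_small_n", "asymptotic", "permutation"):
            raise ConfigurationError(f"unknown p_method {self.p_method!r}")
        if self.by_family_mode not in ("per_category", "joint"):
            raise ConfigurationError(f"unknown by_family_mode {self.by_family_mode!r}")


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov machinery


def _ks_d_numerator(group: np.ndarray, background: np.ndarray) -> int:
    """Exact integer numerator of D: max |A*m - B*n| over pooled points.

    A and B are cumulative counts of group/background values <= x at each
    pooled sample point (right-continuous ECDFs; ties need no special
    handling because both ECDFs jump at the shared point).
    """
    n, m = len(group), len(background)
    g = np.sort(group)
    b = np.sort(background)
    pooled = np.concatenate([g, b])
    a_counts = np.searchsorted(g, pooled, side="right")
    b_counts = np.searchsorted(b, pooled, side="right")
    return int(np.max(np.abs(a_counts * m - b_counts * n)))


def _exact_conditional_pvalue(
    group: np.ndarray, background: np.ndarray, d_num: int
) -> float:
    """P(D >= d_obs) over all C(n+m, n) assignments of the pooled values.

    DP over the distinct pooled values: state = number of pooled items
    assigned to the group so far; weight = number of assignments.  Paths
    are pruned the moment an ECDF boundary reaches |A*m - B*n| >= d_num,
    so the surviving mass is P(D < d_obs).  All arithmetic is integer,
    hence exact.
    """
    n, m = len(group), len(background)
    pooled = np.concatenate([group, background])
    values, counts = np.unique(pooled, return_counts=True)
    if d_num <= 0:
        return 1.0
    dp: dict[int, int] = {0: 1}
    cum = 0
    for c in counts.tolist():
        cum += c
        ndp: dict[int, int] = {}
        for a_prev, w in dp.items():
            for a in range(c + 1):
                a_tot = a_prev + a
                if a_tot > n or (cum - a_tot) > m:
                    continue
                if abs(a_tot * m - (cum - a_tot) * n) >= d_num:
                    continue  # boundary reached d_obs: path counted in p
                ndp[a_tot] = ndp.get(a_tot, 0) + w * comb(c, a)
        dp = ndp
        if not dp:
            return 1.0
    surviving = sum(dp.values())  # only the A=n state can survive to the end
    total = comb(n + m, n)
    return 1.0 - surviving / total


def _permutation_pvalue(
    group: np.ndarray,
    background: np.ndarray,
    d_num: int,
    rounds: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo permutation p with the +1 finite-sample correction."""
    n = len(group)
    pooled = np.concatenate([group, background])
    hits = 0
    for _ in range(rounds):
        rng.shuffle(pooled)
        if _ks_d_numerator(pooled[:n], pooled[n:]) >= d_num:
            hits += 1
    return (hits + 1) / (rounds + 1)


def ks_two_sample(
    group: Sequence[float],
    background: Sequence[float],
    method: str = "auto",
    permutation_rounds: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    Returns ``(D, p)`` where D is the supremum of the absolute ECDF
    difference over the pooled sample points.  ``method``: ``auto``
    chooses the exact conditional null when min(n, m) <= 25, else the
    asymptotic Kolmogorov distribution; ``permutation`` estimates the
    same conditional null by Monte Carlo (reference oracle).
    """
    g = np.asarray(group, dtype=float)
    b = np.asarray(background, dtype=float)
    if g.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    n, m = g.size, b.size
    d_num = _ks_d_numerator(g, b)
    d = d_num / (n * m)
    if method == "auto":
        method = "exact_small_n" if min(n, m) <= EXACT_N_LIMIT else "asymptotic"
    if method == "exact_small_n":
        p = _exact_conditional_pvalue(g, b, d_num)
    elif method == "asymptotic":
        p = float(scipy.stats.ks_2samp(g, b, method="asymp").pvalue)
    elif method == "permutation":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        p = _permutation_pvalue(g, b, d_num, permutation_rounds, rng)
    else:
        raise ConfigurationError(f"unknown KS method {method!r}")
    return d, min(float(p), 1.0)


# ---------------------------------------------------------------------------
# multiple testing


def adjust_benjamini_yekutieli(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment.

    p_adj(i) = min over j >= i (sorted order) of p(j) * m * c(m) / j with
    c(m) = sum_{k=1..m} 1/k, clipped to 1; output matches input order.
    Valid under arbitrary dependence among the tests, which matters here
    because features share carrier proteins.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def classify_enrichment(
    results: pd.DataFrame, config: EnrichmentConfig
) -> pd.DataFrame:
    """Set the ``enriched`` flag: significant AND shifted towards EVs."""
    p_col = "p_adj" if config.apply_adjustment_to_threshold else "p_raw"
    out = results.copy()
    out["enriched"] = (out[p_col] < config.alpha) & (
        out["median_group"] > out["median_all"]
    )
    return out


# ---------------------------------------------------------------------------
# the per-dataset enrichment run


def run_enrichment(
    catalog: FeatureCatalog,
    ratios: pd.Series,
    config: EnrichmentConfig | None = None,
) -> pd.DataFrame:
    """Test every catalog feature against the background of one dataset.

    ``ratios`` holds the per-protein log10 EV:cell ratios of the dataset;
    the catalog should already be size-filtered against this protein set
    (features falling below ``min_group_size`` after intersection are
    skipped defensively).  Returns one row per feature with the fixed
    :data:`RESULT_COLUMNS`, BY-corrected within category families and
    sorted by (p_adj, category, name) for determinism.
    """
    config = config or EnrichmentConfig()
    median_all_ref = float(ratios.median()) if len(ratios) else float("nan")
    protein_set = set(ratios.index)
    all_values = ratios.to_numpy(dtype=float)

    rows: list[dict] = []
    perm_rng = np.random.default_rng(config.permutation_seed)
    for key in sorted(catalog.features):
        carriers = sorted(catalog.carriers_of(key) & protein_set)
        if len(carriers) < config.min_group_size:
            continue
        group = ratios.loc[carriers].to_numpy(dtype=float)
        if config.background_mode == "all_excluding_carriers":
            background = ratios.drop(index=carriers).to_numpy(dtype=float)
        else:
            background = all_values
        if background.size == 0:
            continue
        d, p_raw = ks_two_sample(
            group,
            background,
            method=config.p_method,
            permutation_rounds=config.permutation_rounds,
            rng=perm_rng,
        )
        rows.append(
            {
                "category": key[0],
                "name": key[1],
                "family": catalog.family(key),
                "n_carriers": len(carriers),
                "D": d,
                "p_raw": p_raw,
                "median_group": float(np.median(group)),
                "median_all": float(np.median(background))
                if config.background_mode == "all_excluding_carriers"
                else median_all_ref,
            }
        )
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    df = pd.DataFrame(rows)

    df["p_adj"] = np.nan
    if config.by_family_mode == "joint":
        df["p_adj"] = adjust_benjamini_yekutieli(df["p_raw"].to_numpy())
    else:
        for _, idx in df.groupby("family").groups.items():
            df.loc[idx, "p_adj"] = adjust_benjamini_yekutieli(
                df.loc[idx, "p_raw"].to_numpy()
            )
    df = classify_enrichment(df, config)
    df = df.sort_values(
        ["p_adj", "category", "name"], kind="mergesort"
    ).reset_index(drop=True)
    return df[RESULT_COLUMNS]


def write_results(results: pd.DataFrame, tsv_path: str | Path) -> None:
    """Write a result table as TSV (6 significant digits) and JSON twin."""
    tsv_path = Path(tsv_path)
    results.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    json_path = tsv_path.with_suffix(".json")
    results.to_json(json_path, orient="records", indent=2)
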