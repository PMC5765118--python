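"""Permutation-based differential testing for proteins and IR ratios.

The study design is triplicates per condition, which leaves only
C(6,3) = 20 distinct two-group label assignments.  A per-feature
permutation test therefore cannot produce p-values below 0.05, so the
default test pools permuted statistics across all features into one null
distribution (features are exchangeable under the null on a common scale:
log2 intensities for proteins, IR ratios for introns).  An exact
per-feature enumeration over the 20 assignments is kept as an audit mode.

The statistic is a variance-stabilized two-sample t:

    t = (mean_a - mean_b) / (s0 + sp * sqrt(1/n_a + 1/n_b))

with sp the pooled standard deviation and s0 a small constant offset
(default: the median pooled standard error across features, the
SAM/Perseus convention).  With only 4 residual degrees of freedom the
plain Student t has an extremely heavy-tailed permutation null — a single
low-variance feature dominates the pooled tail — and the offset bounds the
denominator away from zero so that large, consistent effects separate
cleanly from the null.  Setting ``s0=0`` recovers the plain Student t.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .annotation_io import QuantTable


@dataclass
class DiffTestConfig:
    """Thresholds and permutation settings for differential calling.

    ``fc_cutoff_protein`` / ``fc_cutoff_rna`` are linear ratios (a protein is
    called changed only when treated/control >= 1.2 or <= 1/1.2).  ``s0`` is
    the variance-stabilizing offset of the permutation statistic: a float, or
    ``"median"`` for the median pooled standard error across features.
    """

    n_perm: int = 10_000
    alpha: float = 0.01
    adjust: str = "bonferroni"     # protein-level adjustment
    adjust_ir: str = "bh_fdr"      # intron-level adjustment
    fc_cutoff_protein: float = 1.2
    fc_cutoff_rna: float = 1.5
    fdr_rna: float = 0.05
    fdr_ir: float = 0.01
    s0: float | str = "median"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.fc_cutoff_protein > 1 and self.fc_cutoff_rna > 1):
            raise ValueError("fold-change cutoffs must be > 1 (linear ratios)")
        for level in (self.alpha, self.fdr_rna, self.fdr_ir):
            if not 0 < level < 1:
                raise ValueError("significance levels must be in (0, 1)")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _stat(X: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray, s0: float) -> np.ndarray:
    """Variance-stabilized two-sample t per row of X (features x samples)."""
    na, nb = len(a_idx), len(b_idx)
    xa, xb = X[:, a_idx], X[:, b_idx]
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    denom = s0 + sp * np.sqrt(1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                     np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    return t


def resolve_s0(X: np.ndarray, a_idx, b_idx, s0: float | str) -> float:
    if s0 == "median":
        na, nb = len(a_idx), len(b_idx)
        va = X[:, a_idx].var(axis=1, ddof=1)
        vb = X[:, b_idx].var(axis=1, ddof=1)
        sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        return float(np.median(sp) * np.sqrt(1.0 / na + 1.0 / nb))
    return float(s0)


def permutation_test(
    values: pd.DataFrame,
    labels: dict[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    config: DiffTestConfig | None = None,
) -> pd.DataFrame:
    """Pooled-null permutation test of group_a vs group_b per feature.

    ``values`` is features x samples; ``labels`` maps sample -> group.  The
    observed statistic of each feature is compared against permuted
    statistics pooled over all features and ``n_perm`` random relabelings
    (label assignments equal to the observed grouping or its mirror are
    excluded, so the null is built from genuinely mixed groups).  p-values
    use add-one smoothing and are deterministic given ``config.seed``.

    Returns a DataFrame indexed by feature with ``t_stat`` and ``p_perm``.
    """
    config = config or DiffTestConfig()
    labels = dict(labels)
    cols = [s for s in values.columns if labels.get(s) in (group_a, group_b)]
    a_idx = np.array([i for i, s in enumerate(cols) if labels[s] == group_a])
    b_idx = np.array([i for i, s in enumerate(cols) if labels[s] == group_b])
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("each group needs >= 2 samples for a permutation t-test")
    X = values[cols].to_numpy(dtype=float)
    s0 = resolve_s0(X, a_idx, b_idx, config.s0)

    t_obs = _stat(X, a_idx, b_idx, s0)
    abs_obs = np.abs(t_obs)
    order = np.argsort(abs_obs)
    sorted_obs = abs_obs[order]

    rng = np.random.default_rng(config.seed)
    n = len(cols)
    na = len(a_idx)
    observed_set = frozenset(a_idx.tolist())
    counts = np.zeros(len(abs_obs), dtype=np.int64)
    n_pooled = 0
    for _ in range(config.n_perm):
        while True:
            perm = rng.permutation(n)
            pa = frozenset(perm[:na].tolist())
            if pa != observed_set and pa != frozenset(range(n)) - observed_set:
                break
        t_star = np.abs(_stat(X, perm[:na], perm[na:], s0))
        t_star.sort()
        # for each observed |t|, how many permuted stats are >= it
        counts += len(t_star) - np.searchsorted(t_star, sorted_obs, side="left")
        n_pooled += len(t_star)
    p_sorted = (1.0 + counts) / (1.0 + n_pooled)
    p = np.empty_like(p_sorted)
    p[order] = p_sorted
    return pd.DataFrame({"t_stat": t_obs, "p_perm": p}, index=values.index)


def exact_permutation_test(
    values: pd.DataFrame,
    labels: dict[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    s0: float | str = 0.0,
) -> pd.DataFrame:
    """Per-feature exhaustive permutation test (audit mode).

    Enumerates every assignment of samples into groups of the observed sizes
    (20 for 3v3, identity included) and reports the per-feature fraction of
    assignments with |t*| >= |t|.  With triplicates the smallest attainable
    p is 0.1 (the identity and its mirror always tie), which is why the
    pooled test above is the default.
    """
    labels = dict(labels)
    cols = [s for s in values.columns if labels.get(s) in (group_a, group_b)]
    a_idx = np.array([i for i, s in enumerate(cols) if labels[s] == group_a])
    b_idx = np.array([i for i, s in enumerate(cols) if labels[s] == group_b])
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("each group needs >= 2 samples for a permutation t-test")
    X = values[cols].to_numpy(dtype=float)
    s0_val = resolve_s0(X, a_idx, b_idx, s0)
    t_obs = _stat(X, a_idx, b_idx, s0_val)
    abs_obs = np.abs(t_obs)
    n = len(cols)
    count = np.zeros_like(abs_obs)
    total = 0
    for combo in combinations(range(n), len(a_idx)):
        pa = np.array(combo)
        pb = np.array([i for i in range(n) if i not in combo])
        t_star = np.abs(_stat(X, pa, pb, s0_val))
        count += (t_star >= abs_obs) | np.isclose(t_star, abs_obs)
        total += 1
    return pd.DataFrame({"t_stat": t_obs, "p_perm": count / total}, index=values.index)


def adjust_p(p_values, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` or ``bh_fdr`` (BH step-up)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    sm_method = {"bonferroni": "bonferroni", "bh_fdr": "fdr_bh"}[method]
    return multipletests(p, method=sm_method)[1]


# ---------------------------------------------------------------------------
# summaries and calls
# ---------------------------------------------------------------------------

def log2_median_summary(table: QuantTable, group: str) -> pd.Series:
    """log2 of the per-feature median intensity across a group's replicates."""
    samples = table.samples_in(group)
    if not samples:
        raise ValueError(f"group {group!r} has no samples")
    sub = table.values[samples]
    bad = sub.le(0).any(axis=1)
    if bad.any():
        raise ValueError(
            f"non-positive intensity for feature(s) {list(sub.index[bad])[:5]}")
    return np.log2(sub.median(axis=1))


def call_differential_proteins(
    table: QuantTable,
    config: DiffTestConfig,
    treated: str,
    ctrl: str = "CTRL",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Differential proteins, treated vs control.

    The effect is the difference of log2 median summaries (log2 fold-change);
    the permutation test runs on per-sample log2 intensities.  A protein is
    significant when the adjusted p is <= alpha *and* the linear fold-change
    reaches ``fc_cutoff_protein`` in either direction.
    """
    for group in (treated, ctrl):
        if group not in set(table.groups.values()):
            raise ValueError(f"group {group!r} missing from table")
    if (table.values.to_numpy() <= 0).any():
        bad = table.values.index[(table.values <= 0).any(axis=1)]
        raise ValueError(f"non-positive intensity for feature(s) {list(bad)[:5]}")
    log_values = np.log2(table.values)
    effect = log2_median_summary(table, treated) - log2_median_summary(table, ctrl)
    res = permutation_test(log_values, table.groups, treated, ctrl, config)
    p_adj = adjust_p(res["p_perm"], adjust or config.adjust)
    significant = (p_adj <= config.alpha) & (
        np.abs(effect) >= np.log2(config.fc_cutoff_protein))
    out = pd.DataFrame({
        "feature_id": table.values.index,
        "effect": effect.to_numpy(),
        "t_stat": res["t_stat"].to_numpy(),
        "p_perm": res["p_perm"].to_numpy(),
        "p_adj": p_adj,
        "significant": significant.to_numpy(),
    })
    return out


def call_differential_introns(
    ir_matrix: pd.DataFrame,
    groups: dict[str, str],
    config: DiffTestConfig,
    treated: str,
    ctrl: str = "CTRL",
    retained: set[str] | None = None,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Differential intron retention, treated vs control.

    ``ir_matrix`` is introns x samples of IR ratios.  Only introns in
    ``retained`` (those passing the retention filter in at least one group)
    and with complete ratios in the involved samples are tested.  The effect
    is mean(treated IR) - mean(control IR); removal shows as a negative
    effect.  Significance is adjusted-p <= ``fdr_ir`` (BH by default).
    """
    samples = [s for s in ir_matrix.columns if groups.get(s) in (treated, ctrl)]
    sub = ir_matrix[samples]
    if retained is not None:
        sub = sub.loc[sub.index.intersection(pd.Index(sorted(retained)))]
    sub = sub.dropna(axis=0, how="any")
    if sub.empty:
        return pd.DataFrame(columns=[
            "feature_id", "effect", "t_stat", "p_perm", "p_adj", "significant"])
    tr = [s for s in samples if groups[s] == treated]
    ct = [s for s in samples if groups[s] == ctrl]
    effect = sub[tr].mean(axis=1) - sub[ct].mean(axis=1)
    res = permutation_test(sub, groups, treated, ctrl, config)
    p_adj = adjust_p(res["p_perm"], adjust or config.adjust_ir)
    significant = p_adj <= config.fdr_ir
    return pd.DataFrame({
        "feature_id": sub.index,
        "effect": effect.to_numpy(),
        "t_stat": res["t_stat"].to_numpy(),
        "p_perm": res["p_perm"].to_numpy(),
        "p_adj": p_adj,
        "significant": significant,
    })


def removed_introns(diff: pd.DataFrame) -> set[str]:
    """Significantly removed introns: significant with negative effect."""
    hit = diff[(diff["significant"]) & (diff["effect"] < 0)]
    return set(hit["feature_id"])


def introns_per_gene_summary(diff: pd.DataFrame,
                             gene_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Histogram of genes by number of significant introns (k = 1, 2, ...).

    Gene ids default to the ``gene:transcript:index`` intron-id convention.
    """
    sig = diff[diff["significant"].astype(bool)]
    if sig.empty:
        return pd.DataFrame(columns=["n_introns", "n_genes"])
    genes = [
        (gene_of or {}).get(i, str(i).split(":")[0]) for i in sig["feature_id"]]
    per_gene = pd.Series(genes).value_counts()
    hist = per_gene.value_counts().sort_index()
    return pd.DataFrame({"n_introns": hist.index.to_numpy(), "n_genes": hist.to_numpy()})
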