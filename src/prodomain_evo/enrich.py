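"""Perseus-style differential enrichment of proximity-labelling LFQ data.

The pipeline mirrors the standard label-free proximity-labelling workflow:

1. remove potential contaminants, reverse (decoy) hits, and proteins only
   identified by site;
2. log2-transform LFQ intensities (MaxQuant codes absent values as 0,
   which is treated as missing);
3. keep rows where at least one experimental group has a valid value in
   all of its replicates;
4. impute remaining missing values per sample column from a downshifted
   normal distribution, N(mean - downshift*SD, (width*SD)^2), emulating
   left-censored (missing-not-at-random) LFQ missingness;
5. PCA of the samples, and a two-sample test moderated SAM-style:
   d = (mean_target - mean_control) / (se_pooled + s0), with the
   significance threshold on |d| set by balanced group-label permutations
   so that the estimated FDR (pi0-adjusted median permutation false
   positives over observed positives) stays at or below the target.

Defaults follow the study conditions: 4-vs-4 replicates, s0 = 2,
FDR = 0.01, imputation width 0.3 / downshift 1.8 sample SDs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

FLAG_COLUMNS = ("Potential contaminant", "Reverse", "Only identified by site")


@dataclass
class EnrichConfig:
    """Tunables of the enrichment pipeline."""

    s0: float = 2.0
    fdr: float = 0.01
    imputation_width: float = 0.3  # fraction of per-sample SD
    imputation_downshift: float = 1.8  # in per-sample SDs
    max_permutations: int = 1000  # subsample cap for designs larger than 4v4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr must lie in (0, 1]")
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")


@dataclass
class IntensityTable:
    """Protein-by-sample LFQ intensities plus row flags and group labels."""

    intensities: pd.DataFrame  # proteins x samples; NaN where missing
    flags: pd.DataFrame  # boolean, columns = FLAG_COLUMNS
    groups: dict[str, str]  # sample name -> group label

    def __post_init__(self) -> None:
        if set(self.groups) != set(self.intensities.columns):
            raise ValueError("group labels must cover exactly the sample columns")
        if len(set(self.groups.values())) != 2:
            raise ValueError("exactly two group labels are required")
        if not self.flags.index.equals(self.intensities.index):
            raise ValueError("flags and intensities must share the protein index")

    def group_columns(self, label: str) -> list[str]:
        return [s for s in self.intensities.columns if self.groups[s] == label]


def read_protein_groups(
    path: str | Path,
    groups: dict[str, str],
    *,
    id_column: str = "Protein IDs",
    zero_is_missing: bool = True,
) -> IntensityTable:
    """Read a MaxQuant proteinGroups-dialect TSV.

    Sample intensities come from ``LFQ intensity <name>`` columns; flag
    columns ("Potential contaminant", "Reverse", "Only identified by
    site") use "+" for true.  With ``zero_is_missing`` (the MaxQuant
    convention) zero intensities become NaN.
    """
    df = pd.read_csv(path, sep="\t")
    if id_column not in df.columns:
        raise ValueError(f"missing id column {id_column!r}")
    prefix = "LFQ intensity "
    sample_cols = {c[len(prefix) :]: c for c in df.columns if c.startswith(prefix)}
    missing = sorted(set(groups) - set(sample_cols))
    if missing:
        raise ValueError(f"samples not found in table: {missing}")
    intensities = df[[sample_cols[s] for s in groups]].copy()
    intensities.columns = list(groups)
    intensities.index = pd.Index(df[id_column], name=id_column)
    intensities = intensities.astype(float)
    if zero_is_missing:
        intensities = intensities.mask(intensities == 0)
    flags = pd.DataFrame(index=intensities.index)
    for col in FLAG_COLUMNS:
        flags[col] = (df[col].fillna("") == "+").to_numpy() if col in df.columns else False
    return IntensityTable(intensities=intensities, flags=flags, groups=dict(groups))


def filter_rows(table: IntensityTable) -> tuple[IntensityTable, dict[str, int]]:
    """Drop rows with any flag set; returns the removal counts per flag."""
    flagged = table.flags.any(axis=1)
    counts = {col: int(table.flags[col].sum()) for col in table.flags.columns}
    counts["removed"] = int(flagged.sum())
    kept = IntensityTable(
        intensities=table.intensities.loc[~flagged].copy(),
        flags=table.flags.loc[~flagged].copy(),
        groups=table.groups,
    )
    return kept, counts


def log2_transform(intensities: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; missing stays missing; nonpositive values error."""
    if (intensities <= 0).any().any():
        raise ValueError("nonpositive intensities present; cannot log2-transform")
    return np.log2(intensities)


def validity_filter(
    intensities: pd.DataFrame,
    groups: dict[str, str],
    min_valid: int | None = None,
) -> pd.DataFrame:
    """Keep rows where at least one group has >= min_valid valid values.

    ``min_valid`` defaults to the full group size, i.e. one group must be
    valid in all of its replicates.
    """
    keep = pd.Series(False, index=intensities.index)
    for label in sorted(set(groups.values())):
        cols = [s for s in intensities.columns if groups[s] == label]
        need = len(cols) if min_valid is None else min_valid
        keep |= intensities[cols].notna().sum(axis=1) >= need
    return intensities.loc[keep]


def impute(
    intensities: pd.DataFrame,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Downshifted-normal imputation, per sample column, on log2 scale.

    Missing entries in each column are drawn from
    N(mean - downshift*SD, (width*SD)^2) with mean/SD from that column's
    observed values.  Deterministic for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = intensities.copy()
    for col in out.columns:
        observed = out[col].dropna()
        n_missing = out[col].isna().sum()
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        mu = observed.mean()
        sd = observed.std(ddof=1)
        draws = rng.normal(mu - downshift * sd, width * sd, size=n_missing)
        out.loc[out[col].isna(), col] = draws
    return out


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray


def pca(intensities: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of samples over centred protein features (samples as points)."""
    X = intensities.T.to_numpy()  # samples x proteins
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples for PCA")
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete (imputed) matrix")
    k = n_components or min(X.shape)
    k = min(k, min(X.shape))
    model = PCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(X)
    df = pd.DataFrame(
        coords,
        index=intensities.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return PcaResult(coordinates=df, explained_variance_ratio=model.explained_variance_ratio_)


def _group_arrays(
    intensities: pd.DataFrame, groups: dict[str, str], target: str, control: str
) -> tuple[np.ndarray, np.ndarray]:
    cols_t = [s for s in intensities.columns if groups[s] == target]
    cols_c = [s for s in intensities.columns if groups[s] == control]
    if len(cols_t) < 2 or len(cols_c) < 2:
        raise ValueError("each group needs at least 2 samples")
    return intensities[cols_t].to_numpy(), intensities[cols_c].to_numpy()


def _d_statistic(X: np.ndarray, idx1: np.ndarray, idx2: np.ndarray, s0: float):
    """SAM-moderated statistic for one labelling of the pooled columns.

    Returns (difference, pooled standard error, d).  Zero within-group
    variance with s0 = 0 yields +/-inf (flagged infinite, not an error).
    """
    n1, n2 = len(idx1), len(idx2)
    g1, g2 = X[:, idx1], X[:, idx2]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v2 = g2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / (se + s0)
        zero_den = (se + s0) == 0
        d = np.where(zero_den, np.sign(diff) * np.inf, d)
        d = np.where(zero_den & np.isclose(diff, 0), 0.0, d)
    return diff, se, d


def s0_test(
    intensities: pd.DataFrame,
    groups: dict[str, str],
    s0: float,
    target: str,
    control: str,
) -> pd.DataFrame:
    """Per-protein moderated statistic d = diff / (se_pooled + s0).

    With s0 = 0, d is the classical equal-variance two-sample t statistic.
    Also reports the classical t and its two-tailed Student p-value.
    """
    Xt, Xc = _group_arrays(intensities, groups, target, control)
    X = np.hstack([Xt, Xc])
    n1, n2 = Xt.shape[1], Xc.shape[1]
    idx1 = np.arange(n1)
    idx2 = np.arange(n1, n1 + n2)
    diff, se, d = _d_statistic(X, idx1, idx2, s0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.sign(diff) * np.inf)
    p = 2 * stats.t.sf(np.abs(t), df=n1 + n2 - 2)
    return pd.DataFrame(
        {"difference": diff, "se": se, "d": d, "t": t, "p_value": p},
        index=intensities.index,
    )


def balanced_permutations(
    n1: int, n2: int, max_permutations: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group-label relabelings of n1+n2 pooled columns.

    For equal group sizes, complement-equivalent labelings are collapsed
    by pinning column 0 to pseudo-group 1; the identity labelling is then
    dropped, since it reproduces the observed statistics rather than a
    null draw (34 permutations for the 4v4 design).  Designs with more
    labelings than ``max_permutations`` are subsampled with the run seed.
    """
    n = n1 + n2
    if n1 == n2:
        combos = [c for c in itertools.combinations(range(n), n1) if c[0] == 0]
    else:
        combos = list(itertools.combinations(range(n), n1))
    identity = tuple(range(n1))
    combos = [c for c in combos if c != identity]  # identity is not a null relabeling
    if len(combos) > max_permutations:
        pick = rng.choice(len(combos), size=max_permutations, replace=False)
        combos = [combos[i] for i in sorted(pick)]
    out = []
    for c in combos:
        idx1 = np.array(c)
        idx2 = np.array(sorted(set(range(n)) - set(c)))
        out.append((idx1, idx2))
    return out


@dataclass
class EnrichResult:
    """Outcome of the moderated test with permutation-derived threshold."""

    table: pd.DataFrame
    threshold_d: float
    pi0: float
    n_significant: int
    n_target_enriched: int
    target: str
    control: str
    pca: PcaResult | None = None
    counts: dict[str, int] = field(default_factory=dict)
    config: EnrichConfig | None = None


def permutation_fdr(
    intensities: pd.DataFrame,
    groups: dict[str, str],
    config: EnrichConfig,
    target: str,
    control: str,
) -> EnrichResult:
    """SAM-style symmetric |d| threshold at the target permutation FDR.

    The null distribution of d comes from balanced non-identity
    group-label permutations; pi0 is estimated as the fraction of
    observed d inside the permutation interquartile range divided by 0.5
    (capped at 1).  Expected false positives at a cut c use a
    pseudocount-corrected mean over the B permutations,
    ``FP(c) = (1 + sum_b #{|d*_b| >= c}) / (B + 1)`` (the add-one keeps
    the estimate above the resolution the permutation count can certify),
    and the smallest cut with ``pi0 * FP(c) / #{|d| >= c} <= fdr`` is
    chosen; if no cut qualifies nothing is called and the threshold is
    +inf.
    """
    rng = np.random.default_rng(config.seed)
    base = s0_test(intensities, groups, config.s0, target, control)
    d_obs = base["d"].to_numpy()
    m = len(d_obs)

    Xt, Xc = _group_arrays(intensities, groups, target, control)
    X = np.hstack([Xt, Xc])
    n1 = Xt.shape[1]
    perms = balanced_permutations(n1, Xc.shape[1], config.max_permutations, rng)
    d_perm = np.empty((len(perms), m))
    for b, (idx1, idx2) in enumerate(perms):
        d_perm[b] = _d_statistic(X, idx1, idx2, config.s0)[2]

    q25, q75 = np.quantile(d_perm, [0.25, 0.75])
    pi0 = min(1.0, np.mean((d_obs >= q25) & (d_obs <= q75)) / 0.5) if m else 1.0

    abs_obs = np.sort(np.abs(d_obs))
    abs_perm = np.sort(np.abs(d_perm), axis=1)
    # per candidate cut c = abs_obs[k]: positives, and false positives per permutation
    n_pos = m - np.searchsorted(abs_obs, abs_obs, side="left")
    fp = np.empty((len(perms), m))
    for b in range(len(perms)):
        fp[b] = m - np.searchsorted(abs_perm[b], abs_obs, side="left")
    exp_fp = (1.0 + fp.sum(axis=0)) / (len(perms) + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_hat = pi0 * exp_fp / np.maximum(n_pos, 1)
    qualifying = np.flatnonzero((n_pos > 0) & (fdr_hat <= config.fdr))
    # ascending candidates: the smallest qualifying cut maximises discoveries
    threshold = float(abs_obs[qualifying[0]]) if len(qualifying) else math.inf

    significant = np.abs(d_obs) >= threshold
    direction = np.where(base["difference"] > 0, target, control)
    table = base.copy()
    table["significant"] = significant
    table["direction"] = direction
    table["neg_log10_p"] = -np.log10(table["p_value"].clip(lower=1e-300))
    n_target = int((significant & (direction == target)).sum())
    return EnrichResult(
        table=table,
        threshold_d=threshold,
        pi0=float(pi0),
        n_significant=int(significant.sum()),
        n_target_enriched=n_target,
        target=target,
        control=control,
        config=config,
    )


def volcano_export(result: EnrichResult, path: str | Path | None = None) -> pd.DataFrame:
    """Per-protein difference, -log10 p, and significance flag for plotting."""
    out = result.table[
        ["difference", "d", "p_value", "neg_log10_p", "significant", "direction"]
    ].copy()
    out.index.name = result.table.index.name or "protein"
    if path is not None:
        out.to_csv(path, sep="\t")
    return out


def run_enrichment(
    table: IntensityTable,
    config: EnrichConfig,
    target: str,
    control: str,
) -> EnrichResult:
    """Full pipeline: row filters -> log2 -> validity filter -> imputation
    -> PCA + moderated test with permutation FDR.  Stage counts are
    recorded on the result."""
    labels = set(table.groups.values())
    if {target, control} != labels:
        raise ValueError(f"groups {labels} do not match target/control {target}/{control}")
    counts = {"input_rows": len(table.intensities)}
    filtered, removal = filter_rows(table)
    counts.update({f"flagged_{k}": v for k, v in removal.items()})
    counts["after_row_filter"] = len(filtered.intensities)
    logged = log2_transform(filtered.intensities)
    valid = validity_filter(logged, table.groups)
    counts["after_validity_filter"] = len(valid)
    imputed = impute(
        valid,
        width=config.imputation_width,
        downshift=config.imputation_downshift,
        seed=config.seed,
    )
    counts["imputed_values"] = int(valid.isna().sum().sum())
    result = permutation_fdr(imputed, table.groups, config, target, control)
    result.pca = pca(imputed)
    result.counts = counts
    return result
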