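"""Differential statistics for label-free (DIA) protein quantification.

Pipeline order follows standard label-free practice: keep proteins quantified
in at least a fraction of runs, impute remaining missing values from a
down-shifted normal distribution per run, equalise run medians, then test.
Two-group comparisons use Student's t (pooled variance) with a
permutation-based FDR; the responder-stratified procedure computes
drug-vs-DMSO fold changes separately in high- and low-responder lines,
keeps proteins significant in *both* strata (P_high <= 0.05 and
P_low <= 0.05), and reports the interaction effect
log2FC_high-low = log2FC_high − log2FC_low, thresholded at 0.263
(fold change ~1.2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ProteinQuantMatrix:
    """Proteins x sample-runs log2 intensity matrix with run annotations.

    ``runs`` is indexed by run id with columns line_id, treatment,
    replicate; every intensity column must be annotated.
    """

    intensities: pd.DataFrame
    runs: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.intensities.columns if c not in self.runs.index]
        if missing:
            raise ValueError(f"runs lacking annotation: {missing[:5]}")

    @property
    def n_proteins(self) -> int:
        return len(self.intensities)

    @property
    def n_runs(self) -> int:
        return self.intensities.shape[1]

    def select_runs(self, line_ids=None, treatment=None) -> list[str]:
        """Run ids matching the given line set and/or treatment."""
        sel = self.runs.loc[list(self.intensities.columns)]
        if line_ids is not None:
            sel = sel[sel["line_id"].isin(list(line_ids))]
        if treatment is not None:
            sel = sel[sel["treatment"] == treatment]
        return list(sel.index)


def filter_valid(q: ProteinQuantMatrix, min_frac: float = 1 / 3) -> ProteinQuantMatrix:
    """Keep proteins with valid quantification in at least ``min_frac`` of
    total sample runs (boundary inclusive)."""
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must lie in (0, 1]")
    frac = q.intensities.notna().mean(axis=1)
    keep = frac >= min_frac
    return ProteinQuantMatrix(q.intensities.loc[keep].copy(), q.runs)


def impute_missing(
    q: ProteinQuantMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
) -> ProteinQuantMatrix:
    """Replace missing values per run from a down-shifted normal:
    N(mean_run − downshift·sd_run, (width·sd_run)^2), mean/sd over that run's
    observed log2 intensities.  Emulates the low-abundance origin of
    missingness in label-free data."""
    rng = np.random.default_rng(seed)
    vals = q.intensities.to_numpy(dtype=float, copy=True)
    for j, run in enumerate(q.intensities.columns):
        col = vals[:, j]
        obs = col[np.isfinite(col)]
        n_miss = int(np.size(col) - obs.size)
        if n_miss == 0:
            continue
        if obs.size < 2:
            raise ValueError(f"run {run!r} has fewer than 2 observed values")
        mu, sd = obs.mean(), obs.std(ddof=1)
        col[~np.isfinite(col)] = rng.normal(
            mu - downshift * sd, width * sd, size=n_miss
        )
    out = pd.DataFrame(vals, index=q.intensities.index, columns=q.intensities.columns)
    return ProteinQuantMatrix(out, q.runs)


def median_normalize(q: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Equalise run medians: subtract each run's median log2 intensity and
    add back the grand median (median of run medians).  Idempotent."""
    med = q.intensities.median(axis=0)
    grand = float(med.median())
    out = q.intensities - med + grand
    return ProteinQuantMatrix(out, q.runs)


@dataclass
class DifferentialResult:
    """Per-protein two-group comparison (orientation: group1 − group2)."""

    table: pd.DataFrame  # index protein: log2fc, t, p, q, zero_variance
    group1: list[str]
    group2: list[str]
    n_permutations: int
    seed: int | None = None

    def significant(self, q_max: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < q_max]


def _t_pooled(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorised Student t with pooled variance over rows; returns (t, p, df)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p, df


def differential(
    q: ProteinQuantMatrix,
    group1: list[str],
    group2: list[str],
    n_permutations: int = 1000,
    seed: int = 0,
    equal_var: bool = True,
) -> DifferentialResult:
    """Per-protein Student t-test (pooled variance; Welch via
    ``equal_var=False``) of group1 vs group2 with permutation-based FDR.

    The q value of a protein with observed statistic |t| is the median over
    label permutations of (# null |t| >= observed) / (# observed |t| >=
    observed), clipped to [0, 1] and made monotone non-decreasing along the
    p-value ranking.  Proteins with zero variance in both groups are flagged
    and reported with missing p.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs at least 2 runs")
    x1 = q.intensities[list(group1)].to_numpy(dtype=float)
    x2 = q.intensities[list(group2)].to_numpy(dtype=float)
    if equal_var:
        t, p, _ = _t_pooled(x1, x2)
    else:
        t, p = stats.ttest_ind(x1, x2, axis=1, equal_var=False)
    log2fc = x1.mean(axis=1) - x2.mean(axis=1)
    zero_var = (x1.var(axis=1) == 0) & (x2.var(axis=1) == 0)
    t = np.where(zero_var, np.nan, t)
    p = np.where(zero_var, np.nan, p)

    qvals = np.full(t.shape, np.nan)
    ok = np.isfinite(t)
    if n_permutations > 0 and ok.sum() > 0:
        rng = np.random.default_rng(seed)
        obs = np.abs(t[ok])
        order = np.argsort(obs)  # ascending |t|
        obs_sorted = obs[order]
        n_obs = obs.size
        # (# observed |t| >= |t_i|) for each protein
        count_obs = n_obs - np.searchsorted(obs_sorted, obs, side="left")
        pooled = np.hstack([x1, x2])[ok]
        n1 = x1.shape[1]
        ratios = np.empty((n_permutations, n_obs))
        for b in range(n_permutations):
            perm = rng.permutation(pooled.shape[1])
            p1 = pooled[:, perm[:n1]]
            p2 = pooled[:, perm[n1:]]
            if equal_var:
                t_null, _, _ = _t_pooled(p1, p2)
            else:
                t_null, _ = stats.ttest_ind(p1, p2, axis=1, equal_var=False)
            null_sorted = np.sort(np.abs(t_null[np.isfinite(t_null)]))
            count_null = null_sorted.size - np.searchsorted(
                null_sorted, obs, side="left"
            )
            ratios[b] = count_null / count_obs
        q_ok = np.clip(np.median(ratios, axis=0), 0.0, 1.0)
        # enforce monotone non-decreasing q along increasing p (decreasing |t|)
        desc = np.argsort(-obs, kind="stable")
        q_ok[desc] = np.maximum.accumulate(q_ok[desc])
        qvals[ok] = q_ok

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "q": qvals,
            "zero_variance": zero_var,
        },
        index=q.intensities.index,
    )
    return DifferentialResult(
        table=table,
        group1=list(group1),
        group2=list(group2),
        n_permutations=n_permutations,
        seed=seed,
    )


def pooled_volcano(
    q: ProteinQuantMatrix,
    drug_runs: list[str],
    dmso_runs: list[str],
    **kwargs,
) -> DifferentialResult:
    """Pooled drug-vs-DMSO comparison (all lines' sample runs as one group
    each); the result table plots directly as log2FC vs −log10 p."""
    res = differential(q, drug_runs, dmso_runs, **kwargs)
    res.table["neg_log10_p"] = -np.log10(res.table["p"])
    return res


# ---------------------------------------------------------------------------
# responder-stratified differential
# ---------------------------------------------------------------------------

@dataclass
class StratifiedResult:
    """Per-protein stratified records and the thresholds that gated them."""

    records: pd.DataFrame
    high_lines: list[str]
    low_lines: list[str]
    drug: str
    fc_threshold: float
    p_max: float

    @property
    def surviving(self) -> pd.DataFrame:
        r = self.records
        return r[r["pass_p"] & r["pass_fc"]]


def assemble_stratified_records(
    high: pd.DataFrame,
    low: pd.DataFrame,
    fc_threshold: float = 0.263,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Combine high- and low-stratum differential tables into stratified
    records: log2FC_high-low = FC_high − FC_low, pass_p iff both strata have
    p <= p_max, pass_fc iff |log2FC_high-low| > fc_threshold."""
    idx = high.index.intersection(low.index)
    rec = pd.DataFrame(
        {
            "fc_high": high.loc[idx, "log2fc"],
            "p_high": high.loc[idx, "p"],
            "fc_low": low.loc[idx, "log2fc"],
            "p_low": low.loc[idx, "p"],
        }
    )
    rec["log2fc_high_low"] = rec["fc_high"] - rec["fc_low"]
    rec["pass_p"] = (rec["p_high"] <= p_max) & (rec["p_low"] <= p_max)
    rec["pass_fc"] = rec["log2fc_high_low"].abs() > fc_threshold
    return rec


def stratified_differential(
    q: ProteinQuantMatrix,
    high_lines: list[str],
    low_lines: list[str],
    drug: str,
    control: str = "DMSO",
    fc_threshold: float = 0.263,
    p_max: float = 0.05,
    min_runs_per_condition: int = 2,
    equal_var: bool = True,
) -> StratifiedResult:
    """Drug-vs-DMSO differential computed separately within high- and
    low-responder lines (replicate runs of both lines of a stratum pooled as
    one group), gated on significance in both strata and on the interaction
    fold change."""
    groups = {}
    for name, lines in (("high", high_lines), ("low", low_lines)):
        for treatment in (drug, control):
            runs = q.select_runs(line_ids=lines, treatment=treatment)
            for line in lines:
                if not q.select_runs(line_ids=[line], treatment=treatment):
                    raise ValueError(
                        f"no {treatment!r} runs for line {line!r} ({name} stratum)"
                    )
            if len(runs) < min_runs_per_condition:
                raise ValueError(f"too few {treatment!r} runs in {name} stratum")
            groups[(name, treatment)] = runs

    res_high = differential(
        q, groups[("high", drug)], groups[("high", control)],
        n_permutations=0, equal_var=equal_var,
    )
    res_low = differential(
        q, groups[("low", drug)], groups[("low", control)],
        n_permutations=0, equal_var=equal_var,
    )
    records = assemble_stratified_records(
        res_high.table, res_low.table, fc_threshold=fc_threshold, p_max=p_max
    )
    return StratifiedResult(
        records=records,
        high_lines=list(high_lines),
        low_lines=list(low_lines),
        drug=drug,
        fc_threshold=fc_threshold,
        p_max=p_max,
    )


def heatmap_matrix(
    records: pd.DataFrame,
    q: ProteinQuantMatrix,
    lines: list[str],
    drug: str,
    control: str = "DMSO",
    k: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Per-line drug-vs-DMSO log2 fold changes of the surviving proteins,
    z-scored per protein row (mean 0, SD 1).

    Rows with zero SD (identical fold changes across lines) cannot be
    z-scored; they are excluded with a warning.  With ``k`` set, rows are
    clustered by Euclidean k-means (fixed seed) and labels returned.
    """
    if records.empty:
        raise ValueError("no surviving proteins to plot")
    if len(lines) < 2:
        raise ValueError("z-scoring needs at least 2 lines")
    fcs = {}
    for line in lines:
        drug_runs = q.select_runs(line_ids=[line], treatment=drug)
        ctrl_runs = q.select_runs(line_ids=[line], treatment=control)
        if not drug_runs or not ctrl_runs:
            raise ValueError(f"line {line!r} lacks {drug!r} or {control!r} runs")
        fcs[line] = (
            q.intensities.loc[records.index, drug_runs].mean(axis=1)
            - q.intensities.loc[records.index, ctrl_runs].mean(axis=1)
        )
    fc = pd.DataFrame(fcs)
    sd = fc.std(axis=1, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} proteins with identical fold changes "
            "across lines excluded from z-scored heatmap"
        )
        fc = fc[~degenerate]
        sd = sd[~degenerate]
    z = fc.sub(fc.mean(axis=1), axis=0).div(sd, axis=0)
    labels = None
    if k is not None:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = km.fit_predict(z.to_numpy())
    return z, labels
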