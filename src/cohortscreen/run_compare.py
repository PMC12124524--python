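"""Cross-run reproducibility of the screen.

For every drug-donor pair shared between two assay runs we compute the
first Wasserstein (Earth Mover) distance between the runs' well-level
robust-z value distributions, feature by feature.  DMSO-vs-DMSO distances
between the runs provide the reference band: a drug whose per-feature median
EMDs sit inside that band varies between runs no more than the assay
controls do.  Paired induction matrices over the shared drugs/donors give a
second, scalar view of reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import RobustZTable
from .phenotype import induction
from .screen_data import CONTROL_DRUG, WellFeatureTable, aggregate


def emd_1d(sample_a, sample_b) -> float:
    """First Wasserstein distance between two empirical distributions with
    uniform weights (sorted-quantile formulation; symmetric, >= 0)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("emd_1d requires two non-empty samples")
    return float(stats.wasserstein_distance(a, b))


def emd_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise 1-D EMD between two matrices (rows = samples).

    Exact quantile-segment evaluation shared across columns, vectorised for
    the per-feature sweeps of :func:`compare_runs`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("emd_columns expects two (n_samples x n_columns) arrays")
    m, n = a.shape[0], b.shape[0]
    if m == 0 or n == 0:
        raise ValueError("emd_columns requires non-empty samples")
    a_sorted = np.sort(a, axis=0)
    b_sorted = np.sort(b, axis=0)
    edges = np.union1d(np.arange(1, m) / m, np.arange(1, n) / n)
    edges = np.concatenate(([0.0], edges, [1.0]))
    seg_len = np.diff(edges)
    mid = (edges[:-1] + edges[1:]) / 2.0
    ia = np.minimum((mid * m).astype(int), m - 1)
    ib = np.minimum((mid * n).astype(int), n - 1)
    return (seg_len[:, None] * np.abs(a_sorted[ia, :] - b_sorted[ib, :])).sum(axis=0)


@dataclass
class RunComparison:
    """Per-feature EMDs between two runs plus paired induction summaries."""

    pair_emd: pd.DataFrame  # drug_id, donor_id, feature, emd
    dmso_emd: pd.DataFrame  # donor_id, feature, emd (control reference)
    drug_feature_median: pd.DataFrame  # drug_id, feature, median_emd (over donors)
    reference_band: float  # e.g. 95th percentile of DMSO-vs-DMSO EMDs
    frac_within_band: float
    induction_a: pd.DataFrame
    induction_b: pd.DataFrame
    induction_correlation: float


def _wells_by_pair(table: WellFeatureTable, feats: list[str]):
    out = {}
    for (donor, drug), sub in table.data.groupby(["donor_id", "drug_id"]):
        out[(donor, drug)] = sub[feats].to_numpy(dtype=float)
    return out


def compare_runs(
    run_a: RobustZTable | WellFeatureTable,
    run_b: RobustZTable | WellFeatureTable,
    features: list[str] | None = None,
    sigma: float = 2.0,
    band_quantile: float = 0.95,
    seed: int = 0,
) -> RunComparison:
    """Compare two normalized well-level runs over their shared drug-donor
    pairs.

    The DMSO reference EMDs are computed on subsamples of each donor's DMSO
    wells matched in size to the typical drug condition (so the reference
    band reflects the same sampling noise as the drug EMDs).  The paired
    induction matrices are computed per run after median aggregation to
    donor_drug level and correlated over the shared cells.
    """
    ta = run_a.table if isinstance(run_a, RobustZTable) else run_a
    tb = run_b.table if isinstance(run_b, RobustZTable) else run_b
    feats = list(features) if features is not None else [
        f for f in ta.feature_names if f in set(tb.feature_names)
    ]
    if not feats:
        raise ValueError("no shared features between runs")

    wells_a = _wells_by_pair(ta, feats)
    wells_b = _wells_by_pair(tb, feats)
    shared = [
        k for k in wells_a if k in wells_b and k[1] != CONTROL_DRUG
    ]
    if not shared:
        raise ValueError("runs share no (donor, drug) pairs")

    rows = []
    n_drug_wells = []
    for donor, drug in sorted(shared):
        e = emd_columns(wells_a[(donor, drug)], wells_b[(donor, drug)])
        n_drug_wells.append(
            min(len(wells_a[(donor, drug)]), len(wells_b[(donor, drug)]))
        )
        rows.append(
            pd.DataFrame(
                {"drug_id": drug, "donor_id": donor, "feature": feats, "emd": e}
            )
        )
    pair_emd = pd.concat(rows, ignore_index=True)

    # control reference: DMSO vs DMSO per donor, subsampled to the drug well
    # count so band and drug EMDs share the same sampling noise
    rng = np.random.default_rng(seed)
    n_ref = int(np.median(n_drug_wells))
    dmso_rows = []
    shared_donors = sorted({d for d, _ in shared})
    for donor in shared_donors:
        ka, kb = (donor, CONTROL_DRUG), (donor, CONTROL_DRUG)
        if ka not in wells_a or kb not in wells_b:
            continue
        xa, xb = wells_a[ka], wells_b[kb]
        if len(xa) > n_ref:
            xa = xa[rng.choice(len(xa), size=n_ref, replace=False)]
        if len(xb) > n_ref:
            xb = xb[rng.choice(len(xb), size=n_ref, replace=False)]
        e = emd_columns(xa, xb)
        dmso_rows.append(
            pd.DataFrame({"donor_id": donor, "feature": feats, "emd": e})
        )
    if not dmso_rows:
        raise ValueError("no shared donors with DMSO wells in both runs")
    dmso_emd = pd.concat(dmso_rows, ignore_index=True)

    drug_feature_median = (
        pair_emd.groupby(["drug_id", "feature"], sort=True)["emd"]
        .median()
        .rename("median_emd")
        .reset_index()
    )
    band = float(np.quantile(dmso_emd["emd"], band_quantile))
    frac_within = float((drug_feature_median["median_emd"] <= band).mean())

    ind_a = induction(aggregate(ta, "donor_drug"), sigma=sigma, features=feats)
    ind_b = induction(aggregate(tb, "donor_drug"), sigma=sigma, features=feats)
    donors = sorted({d for d, _ in shared})
    drugs = sorted({g for _, g in shared})
    va = ind_a.values.reindex(index=donors, columns=drugs)
    vb = ind_b.values.reindex(index=donors, columns=drugs)
    flat_a, flat_b = va.to_numpy().ravel(), vb.to_numpy().ravel()
    ok = np.isfinite(flat_a) & np.isfinite(flat_b)
    if ok.sum() >= 2 and np.std(flat_a[ok]) > 0 and np.std(flat_b[ok]) > 0:
        r = float(np.corrcoef(flat_a[ok], flat_b[ok])[0, 1])
    else:
        r = float("nan")
    return RunComparison(
        pair_emd=pair_emd,
        dmso_emd=dmso_emd,
        drug_feature_median=drug_feature_median,
        reference_band=band,
        frac_within_band=frac_within,
        induction_a=va,
        induction_b=vb,
        induction_correlation=r,
    )
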