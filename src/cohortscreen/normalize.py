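"""Robust-Z plate normalization against DMSO carrier wells, and the two
feature-reduction filters (coefficient of variation, Spearman redundancy).

Each plate's DMSO wells define a per-feature center (median, µ) and spread
(median absolute deviation, M); every well on that plate is scaled as
z = (x − µ) / (mad_scale · M).  With the default ``mad_scale`` of 1.4826 the
MAD is a consistent estimator of the SD under normality, so z reads as "number
of standard deviations away from the DMSO phenotype".  ``mad_scale=1`` gives
the literal (x − µ)/M formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen_data import CONTROL_DRUG, META_COLUMNS, WellFeatureTable

#: MAD -> SD consistency constant under normality (1/Phi^-1(3/4)).
MAD_TO_SD = 1.4826


@dataclass
class RobustZTable:
    """Normalized table plus the per-plate DMSO statistics that produced it."""

    table: WellFeatureTable
    plate_stats: pd.DataFrame  # long: run_id, plate_id, feature, center, spread
    mad_scale: float
    #: features with zero or undefined MAD on some plate; z is NaN there and
    #: these features are excluded from downstream retained sets
    degenerate_features: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return self.table.feature_names

    def retained_features(self) -> list[str]:
        bad = set(self.degenerate_features)
        return [f for f in self.table.feature_names if f not in bad]


@dataclass
class FeatureFilterReport:
    """Outcome of one feature filter: what was removed, by what, and why."""

    retained: list[str]
    removed_by_cov: list[tuple[str, float]] = field(default_factory=list)
    removed_zero_mean: list[str] = field(default_factory=list)
    removed_by_spearman: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def removed(self) -> list[str]:
        return (
            [f for f, _ in self.removed_by_cov]
            + list(self.removed_zero_mean)
            + [f for f, _, _ in self.removed_by_spearman]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [(f, "retained", "", np.nan) for f in self.retained]
        rows += [(f, "removed_cov", "", v) for f, v in self.removed_by_cov]
        rows += [(f, "removed_zero_mean", "", np.nan) for f in self.removed_zero_mean]
        rows += [(f, "removed_spearman", p, s) for f, p, s in self.removed_by_spearman]
        return pd.DataFrame(rows, columns=["feature", "status", "partner", "value"])


def robust_z(
    table: WellFeatureTable,
    mad_scale: float = MAD_TO_SD,
    min_dmso_wells: int = 4,
) -> RobustZTable:
    """Normalize every well against its own plate's DMSO wells.

    Raises if any plate lacks DMSO wells (or has fewer than
    ``min_dmso_wells``).  Features whose DMSO MAD is zero on some plate are
    flagged as degenerate: their z values on that plate are undefined (NaN)
    and they are excluded from :meth:`RobustZTable.retained_features`.
    """
    if table.level != "well":
        raise ValueError("robust_z expects a well-level table")
    feats = table.feature_names
    data = table.data.copy()
    z = data[feats].to_numpy(dtype=float, copy=True)
    stats_rows = []
    degenerate: set[str] = set()

    for (run, plate), idx in data.groupby(["run_id", "plate_id"]).groups.items():
        sub = data.loc[idx]
        dmso = sub[sub["drug_id"] == CONTROL_DRUG]
        if dmso.empty:
            raise ValueError(f"plate {plate!r} (run {run!r}) has no DMSO wells")
        if len(dmso) < min_dmso_wells:
            raise ValueError(
                f"plate {plate!r} (run {run!r}) has {len(dmso)} DMSO wells; "
                f"at least {min_dmso_wells} required"
            )
        x = dmso[feats].to_numpy(dtype=float)
        center = np.nanmedian(x, axis=0)
        spread = np.nanmedian(np.abs(x - center), axis=0)
        bad = ~(spread > 0)
        if bad.any():
            degenerate.update(np.array(feats)[bad])
        denom = np.where(bad, np.nan, mad_scale * spread)
        pos = data.index.get_indexer(idx)
        z[pos] = (z[pos] - center) / denom
        for j, f in enumerate(feats):
            stats_rows.append((run, plate, f, center[j], spread[j]))

    out = pd.concat(
        [data[META_COLUMNS].reset_index(drop=True),
         pd.DataFrame(z, columns=feats)],
        axis=1,
    )
    ztable = WellFeatureTable(out, list(feats), level="well")
    plate_stats = pd.DataFrame(
        stats_rows, columns=["run_id", "plate_id", "feature", "center", "spread"]
    )
    return RobustZTable(
        table=ztable,
        plate_stats=plate_stats,
        mad_scale=mad_scale,
        degenerate_features=sorted(degenerate),
    )


def filter_cov(
    table: WellFeatureTable,
    max_cov: float = 0.50,
    features: list[str] | None = None,
) -> FeatureFilterReport:
    """Remove features with coefficient of variation > ``max_cov``.

    CoV = sample SD / |mean|, computed per feature over the pooled DMSO
    carrier wells of the (raw, pre-normalization) table.  Features with mean
    exactly zero have no defined CoV and are removed and reported separately.
    """
    feats = list(features) if features is not None else list(table.feature_names)
    ref = table.data.loc[table.is_control, feats]
    if len(ref) < 3:
        raise ValueError(
            f"need at least 3 DMSO reference wells to estimate CoV, got {len(ref)}"
        )
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    retained, removed, zero_mean = [], [], []
    for f in feats:
        if mean[f] == 0:
            zero_mean.append(f)
            continue
        cov = sd[f] / abs(mean[f])
        if cov > max_cov:
            removed.append((f, float(cov)))
        else:
            retained.append(f)
    return FeatureFilterReport(
        retained=retained, removed_by_cov=removed, removed_zero_mean=zero_mean
    )


def _spearman_matrix(values: pd.DataFrame) -> np.ndarray:
    ranks = values.rank(axis=0, na_option="keep")
    if not values.isna().any().any():
        with np.errstate(invalid="ignore"):
            return np.corrcoef(ranks.to_numpy(), rowvar=False)
    return ranks.corr(method="pearson", min_periods=2).to_numpy()


def filter_spearman(
    table: WellFeatureTable,
    max_abs_s: float = 0.98,
    features: list[str] | None = None,
) -> FeatureFilterReport:
    """Greedy redundancy filter: walking features in table order, drop a
    feature iff its |Spearman correlation| over all wells exceeds
    ``max_abs_s`` with an earlier *retained* feature.  The retained set is
    reproducible and every retained pair satisfies |s| <= ``max_abs_s``.
    """
    feats = list(features) if features is not None else list(table.feature_names)
    if len(feats) <= 1:
        return FeatureFilterReport(retained=feats)
    corr = _spearman_matrix(table.data[feats])
    retained_idx: list[int] = []
    retained: list[str] = []
    removed: list[tuple[str, str, float]] = []
    for j, f in enumerate(feats):
        partner = None
        for i in retained_idx:
            s = corr[i, j]
            if np.isfinite(s) and abs(s) > max_abs_s:
                partner = (feats[i], float(s))
                break
        if partner is None:
            retained_idx.append(j)
            retained.append(f)
        else:
            removed.append((f, partner[0], partner[1]))
    return FeatureFilterReport(retained=retained, removed_by_spearman=removed)


def normalize_and_filter(
    raw: WellFeatureTable,
    mad_scale: float = MAD_TO_SD,
    max_cov: float = 0.50,
    max_abs_s: float = 0.98,
    min_dmso_wells: int = 4,
) -> tuple[RobustZTable, FeatureFilterReport, FeatureFilterReport]:
    """Standard pipeline: robust-Z -> CoV filter (raw DMSO scale) -> Spearman
    redundancy filter (on z values).  Returns the normalized table (restricted
    to surviving features) and both filter reports."""
    zt = robust_z(raw, mad_scale=mad_scale, min_dmso_wells=min_dmso_wells)
    usable = zt.retained_features()
    cov_report = filter_cov(raw, max_cov=max_cov, features=usable)
    sp_report = filter_spearman(
        zt.table, max_abs_s=max_abs_s, features=cov_report.retained
    )
    zt.table = zt.table.subset_features(sp_report.retained)
    return zt, cov_report, sp_report


def verify_dmso_contract(
    zt: RobustZTable, tol: float = 1e-9
) -> tuple[float, float]:
    """Post-condition of the normalization: on every plate and retained
    feature, the DMSO wells' median z is 0 and mad_scale·MAD(z) is 1.

    Returns the worst absolute deviations (median, scaled MAD − 1); raises if
    either exceeds ``tol``.
    """
    feats = zt.retained_features()
    feats = [f for f in feats if f in zt.table.feature_names]
    worst_med, worst_mad = 0.0, 0.0
    data = zt.table.data
    for (_run, _plate), idx in data.groupby(["run_id", "plate_id"]).groups.items():
        sub = data.loc[idx]
        z = sub.loc[sub["drug_id"] == CONTROL_DRUG, feats].to_numpy(dtype=float)
        med = np.nanmedian(z, axis=0)
        mad = np.nanmedian(np.abs(z - med), axis=0) * zt.mad_scale
        worst_med = max(worst_med, float(np.nanmax(np.abs(med))))
        worst_mad = max(worst_mad, float(np.nanmax(np.abs(mad - 1.0))))
    if worst_med > tol or worst_mad > tol:
        raise AssertionError(
            f"DMSO normalization contract violated: |median z| up to {worst_med:g}, "
            f"|scaled MAD − 1| up to {worst_mad:g}"
        )
    return worst_med, worst_mad
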