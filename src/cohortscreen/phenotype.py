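"""Scalar phenotype statistics over normalized screen profiles.

* induction — the screen's headline response statistic: the fraction of
  retained features whose robust z magnitude exceeds a σ cutoff (default 2,
  i.e. >95% certainty under normality) for a drug-donor pair.
* distance-to-control — Euclidean distance between a drug-donor profile and
  the same donor's DMSO profile, with per-drug mean/SD/CoV across donors.
* induction correlation — drug x drug correlation of induction patterns
  across the donor cohort (shared variable-response structure).
* responder stratification — ranking donors by induction for one drug and
  labelling top/bottom k as high/low responders.
* 2-D embeddings (UMAP / PCA) of profiles for MoA-level visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen_data import CONTROL_DRUG, WellFeatureTable


@dataclass
class InductionMatrix:
    """Donors x drugs induction scores in [0, 1]."""

    values: pd.DataFrame  # index donor_id, columns drug_id
    sigma_cutoff: float
    n_features_used: int


def induction(
    ztable: WellFeatureTable,
    sigma: float = 2.0,
    features: list[str] | None = None,
    include_control: bool = False,
) -> InductionMatrix:
    """Induction per (donor, drug): fraction of retained features with
    |z| > sigma.  Missing features are excluded from both numerator and
    denominator of their pair.  Expects a donor_drug-level z table."""
    if ztable.level != "donor_drug":
        raise ValueError("induction expects a donor_drug-level table")
    feats = list(features) if features is not None else list(ztable.feature_names)
    if not feats:
        raise ValueError("no retained features to compute induction over")
    data = ztable.data
    if not include_control:
        data = data[data["drug_id"] != CONTROL_DRUG]
    z = data[feats].to_numpy(dtype=float)
    valid = np.isfinite(z)
    n_valid = valid.sum(axis=1)
    if (n_valid == 0).any():
        raise ValueError("a donor-drug pair has no non-missing features")
    hits = (np.abs(z) > sigma) & valid
    frac = hits.sum(axis=1) / n_valid
    out = data[["donor_id", "drug_id"]].copy()
    out["induction"] = frac
    values = out.pivot_table(
        index="donor_id", columns="drug_id", values="induction", aggfunc="mean"
    )
    return InductionMatrix(values=values, sigma_cutoff=sigma, n_features_used=len(feats))


@dataclass
class DistanceTable:
    """Per-pair Euclidean distance to the donor's DMSO profile, with per-drug
    dispersion statistics across donors."""

    pairs: pd.DataFrame  # donor_id, drug_id, distance
    per_drug: pd.DataFrame  # drug_id, mean, sd, cov


def distance_to_control(
    table: WellFeatureTable,
    features: list[str] | None = None,
) -> DistanceTable:
    """Euclidean distance between each donor-drug profile and that donor's
    DMSO profile, over the given (Spearman-filtered) feature set.  Donors
    lacking a DMSO profile yield missing distances."""
    if table.level != "donor_drug":
        raise ValueError("distance_to_control expects a donor_drug-level table")
    feats = list(features) if features is not None else list(table.feature_names)
    data = table.data
    dmso = (
        data[data["drug_id"] == CONTROL_DRUG]
        .set_index("donor_id")[feats]
    )
    rows = []
    for _, rec in data[data["drug_id"] != CONTROL_DRUG].iterrows():
        donor = rec["donor_id"]
        if donor not in dmso.index:
            rows.append((donor, rec["drug_id"], np.nan))
            continue
        a = rec[feats].to_numpy(dtype=float)
        b = dmso.loc[donor].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        rows.append((donor, rec["drug_id"], float(np.sqrt(np.sum((a[ok] - b[ok]) ** 2)))))
    pairs = pd.DataFrame(rows, columns=["donor_id", "drug_id", "distance"])
    g = pairs.groupby("drug_id")["distance"]
    per_drug = pd.DataFrame(
        {"mean": g.mean(), "sd": g.std(ddof=1)}
    )
    per_drug["cov"] = np.where(
        per_drug["mean"] > 0, per_drug["sd"] / per_drug["mean"], np.nan
    )
    return DistanceTable(pairs=pairs, per_drug=per_drug.reset_index())


def induction_correlation(
    im: InductionMatrix,
    drugs: list[str] | None = None,
    method: str = "pearson",
    min_donors: int = 3,
) -> pd.DataFrame:
    """Drug x drug correlation of induction patterns across donors
    (pairwise-complete).  Drugs with a constant induction vector correlate
    as missing; the diagonal is 1 by convention."""
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    vals = im.values[drugs] if drugs is not None else im.values
    corr = vals.corr(method=method, min_periods=min_donors)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class ResponderStratification:
    """Donors ranked by induction for one drug; top-k high, bottom-k low."""

    drug_id: str
    ranking: pd.Series  # induction indexed by donor, descending
    high: list[str]
    low: list[str]
    k: int
    tie_policy: str = "lexicographic donor_id"


def stratify_responders(
    im: InductionMatrix,
    drug_id: str,
    k: int | None = None,
    quantile: float | None = None,
) -> ResponderStratification:
    """Rank donors by induction for ``drug_id`` (ties broken by donor id) and
    take the top/bottom ``k`` — or the outer ``quantile`` fraction — as
    high/low responders."""
    if drug_id not in im.values.columns:
        raise KeyError(f"drug {drug_id!r} not in induction matrix")
    col = im.values[drug_id].dropna()
    n = len(col)
    if quantile is not None:
        k = int(round(quantile * n))
    if k is None:
        raise ValueError("either k or quantile must be given")
    if k > n // 2:
        raise ValueError(f"k={k} exceeds half of {n} donors")
    ordered = col.sort_index().sort_values(ascending=False, kind="stable")
    high = list(ordered.index[:k])
    # bottom-k with the same lexicographic tie policy
    asc = col.sort_index().sort_values(ascending=True, kind="stable")
    low = list(asc.index[:k])
    return ResponderStratification(
        drug_id=drug_id, ranking=ordered, high=high, low=low, k=k
    )


@dataclass
class EmbeddingResult:
    coords: pd.DataFrame  # donor_id, drug_id, dim1, dim2
    method: str
    params: dict = field(default_factory=dict)
    variance_explained: np.ndarray | None = None


def embed(
    table: WellFeatureTable,
    method: str = "umap",
    features: list[str] | None = None,
    n_neighbors: int = 15,
    min_dist: float = 0.01,
    metric: str = "cosine",
    seed: int = 0,
    include_control: bool = True,
) -> EmbeddingResult:
    """2-D embedding of donor-drug profiles (UMAP with the screen's
    parameters — n_neighbours 15, min_dist 0.01, cosine metric — or PCA,
    which also reports variance explained)."""
    feats = list(features) if features is not None else list(table.feature_names)
    data = table.data
    if not include_control:
        data = data[data["drug_id"] != CONTROL_DRUG]
    x = data[feats].to_numpy(dtype=float)
    if method == "umap":
        if len(x) < n_neighbors:
            raise ValueError(
                f"{len(x)} profiles < n_neighbors={n_neighbors}; "
                "reduce n_neighbors or supply more profiles"
            )
        import umap  # deferred: numba compilation is slow at import

        reducer = umap.UMAP(
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric=metric,
            n_components=2,
            random_state=seed,
        )
        emb = reducer.fit_transform(x)
        var = None
        params = {"n_neighbors": n_neighbors, "min_dist": min_dist, "metric": metric}
    elif method == "pca":
        from sklearn.decomposition import PCA

        pca = PCA(n_components=2, random_state=seed)
        emb = pca.fit_transform(x)
        var = pca.explained_variance_ratio_
        params = {}
    else:
        raise ValueError("method must be umap or pca")
    coords = data[["donor_id", "drug_id"]].reset_index(drop=True).copy()
    coords["dim1"] = emb[:, 0]
    coords["dim2"] = emb[:, 1]
    return EmbeddingResult(
        coords=coords, method=method, params=params, variance_explained=var
    )
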