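"""Recovery and calibration benchmarks run against planted ground truth.

Each function here builds synthetic inputs with known structure, runs the
corresponding pipeline stage end to end, and measures how well the stage
recovers the planted truth (or how well its null calibration matches theory).
They are shared by the test suite and by ``scripts/acceptance.py``.

Problem sizes default to desk-scale versions of the screen design (fewer
donors/drugs/features than the full 28 x 52 x 871 run) so a full benchmark
sweep completes in minutes; effect-size and noise parameters are the
generator defaults throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog

from .normalize import normalize_and_filter, robust_z, verify_dmso_contract
from .phenotype import induction, stratify_responders
from .proteome import (
    filter_valid,
    impute_missing,
    median_normalize,
    differential,
    stratified_differential,
)
from .run_compare import RunComparison, compare_runs, emd_1d
from .screen_data import CONTROL_DRUG, META_COLUMNS, WellFeatureTable, aggregate, well_name
from .synthetic import (
    ProteomeSimConfig,
    ScreenSimConfig,
    generate_proteome,
    generate_screen,
    simulate_truth,
)


# ---------------------------------------------------------------------------
# EMD oracle
# ---------------------------------------------------------------------------

def transport_emd(sample_a, sample_b) -> float:
    """Brute-force first Wasserstein distance via the optimal-transport
    linear program (uniform weights).  Independent reference for
    :func:`cohortscreen.emd_1d`; only sensible for small samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    m, n = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :]).ravel()
    # marginals: rows sum to 1/m, columns to 1/n
    a_eq = np.zeros((m + n, m * n))
    for i in range(m):
        a_eq[i, i * n : (i + 1) * n] = 1.0
    for j in range(n):
        a_eq[m + j, j::n] = 1.0
    b_eq = np.concatenate([np.full(m, 1.0 / m), np.full(n, 1.0 / n)])
    res = linprog(cost, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def emd_oracle_max_error(seed: int = 0, n_cases: int = 1000, max_points: int = 6) -> float:
    """Largest |emd_1d − transport LP| over random small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        m = int(rng.integers(1, max_points + 1))
        n = int(rng.integers(1, max_points + 1))
        a = rng.normal(0, 2, size=m)
        b = rng.normal(0.5, 1, size=n)
        worst = max(worst, abs(emd_1d(a, b) - transport_emd(a, b)))
    return worst


# ---------------------------------------------------------------------------
# normalization calibration
# ---------------------------------------------------------------------------

def dmso_contract_residuals(seed: int = 0) -> tuple[float, float]:
    """Worst per-plate deviations of the DMSO median-z / scaled-MAD contract
    on a default small synthetic run."""
    cfg = ScreenSimConfig(
        n_donors=4, n_drugs=6, n_features=120, n_moa_classes=3,
        wells_per_condition=3, bioreplicates=2, dmso_wells_per_plate=8,
        cells_per_well=(50, 80), seed=seed,
    )
    table, _ = generate_screen(cfg)
    zt = robust_z(table)
    return verify_dmso_contract(zt)


def _gaussian_control_plate(
    rng: np.random.Generator, plate_id: str, n_dmso: int, n_probe: int, n_features: int
) -> pd.DataFrame:
    """One plate of pure-noise wells: DMSO carrier wells plus 'probe' wells
    drawn from the same Gaussian (a DMSO-vs-DMSO comparison in disguise)."""
    feats = [f"feat{i:03d}" for i in range(n_features)]
    rows = []
    for w in range(n_dmso + n_probe):
        is_ctrl = w < n_dmso
        rows.append(
            (
                "nullrun", plate_id, well_name(w),
                f"ctrl-{plate_id}" if is_ctrl else f"probe-{plate_id}-{w - n_dmso:03d}",
                CONTROL_DRUG if is_ctrl else "probe",
                0.0, 1, w + 1, 100,
            )
        )
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    vals = pd.DataFrame(rng.normal(size=(n_dmso + n_probe, n_features)), columns=feats)
    return pd.concat([meta, vals], axis=1)


def null_induction_mean(
    seed: int = 0,
    n_plates: int = 5,
    n_dmso: int = 300,
    n_probe: int = 84,
    n_features: int = 24,
    sigma: float = 2.0,
) -> float:
    """Mean induction of Gaussian null wells against same-plate DMSO.

    With the MAD scaled to SD units, the fraction of |z| > 2 converges to
    2Φ(−2) ≈ 0.0455; the default sizes give 10,000 feature draws.
    """
    rng = np.random.default_rng(seed)
    plates = [
        _gaussian_control_plate(rng, f"plate{p}", n_dmso, n_probe, n_features)
        for p in range(n_plates)
    ]
    data = pd.concat(plates, ignore_index=True)
    feats = [c for c in data.columns if c not in META_COLUMNS]
    table = WellFeatureTable(data, feats, level="well")
    zt = robust_z(table)
    dd = aggregate(zt.table, "donor_drug")
    im = induction(dd, sigma=sigma, features=zt.retained_features())
    return float(im.values.to_numpy().mean())


# ---------------------------------------------------------------------------
# responder stratification recovery
# ---------------------------------------------------------------------------

def _recovery_config(seed: int) -> ScreenSimConfig:
    return ScreenSimConfig(
        n_donors=12, n_drugs=8, n_features=871, n_moa_classes=4,
        wells_per_condition=6, bioreplicates=2, dmso_wells_per_plate=16,
        cells_per_well=(500, 667), seed=seed,
    )


def responder_recovery(seed: int = 0, n_seeds: int = 20) -> float:
    """Mean balanced accuracy of top/bottom-quartile responder recovery.

    For each seed a screen is generated, normalized and filtered; donors are
    stratified per drug by induction rank (k = n_donors/4) and compared with
    the planted magnitude-quartile labels.  Balanced accuracy averages the
    recall of the planted 'high' and 'low' donor sets.
    """
    accs = []
    for s in range(n_seeds):
        cfg = _recovery_config(seed + 17 * s + 1)
        table, truth = generate_screen(cfg)
        zt, _, _ = normalize_and_filter(table)
        dd = aggregate(zt.table, "donor_drug")
        im = induction(dd, features=zt.table.feature_names)
        k = cfg.n_donors // 4
        for drug in cfg.drug_ids:
            strat = stratify_responders(im, drug, k=k)
            labels = truth.responder_label[drug]
            true_high = set(labels[labels == "high"].index)
            true_low = set(labels[labels == "low"].index)
            if not true_high or not true_low:
                continue
            recall_high = len(true_high & set(strat.high)) / len(true_high)
            recall_low = len(true_low & set(strat.low)) / len(true_low)
            accs.append((recall_high + recall_low) / 2)
    return float(np.mean(accs))


def magnitude_induction_spearman(seed: int = 0, n_seeds: int = 5) -> float:
    """Mean Spearman correlation between planted donor magnitude and realized
    induction, per drug, across donors."""
    rhos = []
    for s in range(n_seeds):
        cfg = _recovery_config(seed + 31 * s + 3)
        table, truth = generate_screen(cfg)
        zt, _, _ = normalize_and_filter(table)
        dd = aggregate(zt.table, "donor_drug")
        im = induction(dd, features=zt.table.feature_names)
        for drug in cfg.drug_ids:
            mags = truth.magnitude.iloc[:, truth.moa_of_drug[drug]]
            vals = im.values[drug].reindex(mags.index)
            rho = stats.spearmanr(mags, vals).statistic
            rhos.append(rho)
    return float(np.mean(rhos))


# ---------------------------------------------------------------------------
# proteomics: FDR control and stratified recovery
# ---------------------------------------------------------------------------

def _prepare(q, seed: int):
    q = filter_valid(q)
    q = impute_missing(q, seed=seed)
    return median_normalize(q)


def null_fdr(
    seed: int = 0,
    n_seeds: int = 20,
    n_proteins: int = 800,
    n_permutations: int = 250,
) -> float:
    """Fraction of proteins called at q < 0.05 on fully null proteomes
    (every call is a false positive), averaged over seeds."""
    fracs = []
    for s in range(n_seeds):
        cfg = ProteomeSimConfig(
            n_proteins=n_proteins, n_planted=0, seed=seed + 101 * s + 5
        )
        q, _ = generate_proteome(cfg, None, ["lineA", "lineB"], "drugX")
        q = _prepare(q, seed=seed + s)
        drug_runs = q.select_runs(treatment="drugX")
        dmso_runs = q.select_runs(treatment=CONTROL_DRUG)
        res = differential(
            q, drug_runs, dmso_runs, n_permutations=n_permutations, seed=seed + s
        )
        called = res.table["q"] < 0.05
        fracs.append(called.mean())
    return float(np.mean(fracs))


def stratified_recovery(
    seed: int = 0,
    n_seeds: int = 20,
    n_proteins: int = 1200,
    n_planted: int = 100,
) -> tuple[float, float]:
    """Sensitivity and sign agreement of the stratified differential on
    planted responder-dependent proteins.

    Lines are chosen from the screen ground truth (two planted 'high', two
    planted 'low' responders); a planted protein counts as recovered when it
    survives both the dual p gate and the |log2FC_high-low| > 0.263 gate, and
    its sign agrees when log2FC_high-low matches the planted direction.
    """
    sens, signs = [], []
    for s in range(n_seeds):
        truth = simulate_truth(_recovery_config(seed + 13 * s + 7))
        drug = "drug01"
        labels = truth.responder_label[drug]
        high = sorted(labels[labels == "high"].index)[:2]
        low = sorted(labels[labels == "low"].index)[:2]
        pcfg = ProteomeSimConfig(
            n_proteins=n_proteins, n_planted=n_planted, seed=seed + 23 * s + 11
        )
        q, ptruth = generate_proteome(pcfg, truth, high + low, drug)
        q = _prepare(q, seed=seed + s)
        res = stratified_differential(q, high, low, drug)
        surviving = res.surviving
        planted = ptruth.planted
        recovered = planted.index.intersection(surviving.index)
        sens.append(len(recovered) / len(planted))
        if len(recovered):
            agree = np.sign(surviving.loc[recovered, "log2fc_high_low"]) == np.sign(
                planted.loc[recovered, "effect_high"] - planted.loc[recovered, "effect_low"]
            )
            signs.append(float(agree.mean()))
    return float(np.mean(sens)), float(np.mean(signs))


# ---------------------------------------------------------------------------
# cross-run reproducibility
# ---------------------------------------------------------------------------

def _replicate_config(seed: int, cytotoxic: tuple[str, ...] = ()) -> ScreenSimConfig:
    return ScreenSimConfig(
        n_donors=8, n_drugs=10, n_features=250, n_moa_classes=5,
        wells_per_condition=6, bioreplicates=1, dmso_wells_per_plate=16,
        cells_per_well=(50, 80), cytotoxic_drugs=cytotoxic, seed=seed,
    )


def replicate_run_comparison(
    seed: int = 0, cytotoxic: tuple[str, ...] = ()
) -> RunComparison:
    """Compare two replicate synthetic runs (same planted truth, independent
    noise); optionally inflate the variance of some drugs in the second run
    to emulate cytotoxic compounds."""
    cfg_a = _replicate_config(seed)
    cfg_b = _replicate_config(seed, cytotoxic=cytotoxic)
    run_a, _ = generate_screen(cfg_a, noise_seed=seed + 500_009)
    run_b, _ = generate_screen(cfg_b, noise_seed=seed + 900_007)
    za, cov_rep, sp_rep = normalize_and_filter(run_a)
    zb = robust_z(run_b)
    feats = [f for f in za.table.feature_names if f in set(zb.retained_features())]
    return compare_runs(za, zb.table.subset_features(feats), features=feats, seed=seed)


def cytotoxic_dominance_p(comparison: RunComparison, cytotoxic: tuple[str, ...]) -> float:
    """One-sided Mann-Whitney p that cytotoxic drugs' per-feature median EMDs
    exceed the other drugs'."""
    med = comparison.drug_feature_median
    in_c = med["drug_id"].isin(cytotoxic)
    res = stats.mannwhitneyu(
        med.loc[in_c, "median_emd"], med.loc[~in_c, "median_emd"],
        alternative="greater",
    )
    return float(res.pvalue)
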