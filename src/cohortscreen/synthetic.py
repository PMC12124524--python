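"""Synthetic multi-donor plate screens and DIA-style proteomes with ground truth.

The screen generator emulates the statistical structure of a cohort Cell
Painting screen: donor hiPSC lines plated in rows of a 384-well plate, six
technical replicate wells per drug-donor condition, two bioreplicates, DMSO
carrier wells on every plate, and sparse signed drug signatures whose
*magnitude* varies across donors.  Each drug belongs to a mechanism-of-action
(MoA) class; a donor's sensitivity is drawn per MoA class, so drugs sharing a
target show correlated variable response across the cohort.

The proteome generator emulates triplicate label-free DIA runs per line and
condition: log-normal baseline abundances, planted drug-response proteins whose
log2 shift is scaled by the line's responder status, and intensity-dependent
missingness (low-abundance measurements drop out more often).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen_data import (
    CONTROL_DRUG,
    META_COLUMNS,
    PLATE_COLS,
    WellFeatureTable,
    well_name,
)
from .proteome import ProteinQuantMatrix


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Parameters of the simulated screen.

    Defaults mirror the screen design: 28 donors x 52 drugs (1,456 drug-donor
    pairs), 871 features, 6 technical replicate wells per condition and 2
    bioreplicates, with 500-667 cells per well so that 6,000-8,000 cells
    accrue per drug-donor pair.
    """

    n_donors: int = 28
    n_drugs: int = 52
    n_features: int = 871
    n_moa_classes: int = 8
    #: fraction of features carrying each MoA signature
    signature_sparsity: float = 0.15
    #: |signature| entries drawn uniformly from this range (units: per-feature
    #: noise SDs), spanning sub- and supra-threshold effects so induction
    #: grows smoothly with donor magnitude instead of saturating
    effect_low: float = 0.5
    effect_high: float = 4.5
    #: donor x MoA sensitivity ~ LogNormal(0, magnitude_sigma), median 1
    magnitude_sigma: float = 0.6
    noise_sd: float = 1.0
    #: lognormal spread of per-feature noise scales
    feature_noise_sigma: float = 0.25
    #: per-plate per-feature baseline offsets (batch effect)
    plate_sd: float = 0.3
    #: raw feature baselines drawn uniformly from this positive range
    baseline_range: tuple[float, float] = (8.0, 12.0)
    #: fraction of features with DMSO coefficient of variation > 0.5
    frac_high_cov_features: float = 0.05
    #: fraction of features that near-duplicate another (|Spearman| ~ 1)
    frac_duplicate_features: float = 0.03
    wells_per_condition: int = 6
    bioreplicates: int = 2
    dmso_wells_per_plate: int = 16
    cells_per_well: tuple[int, int] = (500, 667)
    dose_uM: float = 5.0
    #: quantiles of donor magnitude defining low/high responder labels
    responder_quantiles: tuple[float, float] = (0.25, 0.75)
    #: optional donor index with globally elevated response (off by default)
    global_high_donor: int | None = None
    global_high_factor: float = 2.0
    #: drugs with inflated feature variance and reduced cell counts
    cytotoxic_drugs: tuple[str, ...] = ()
    cytotoxic_sd_factor: float = 2.0
    cytotoxic_cell_loss: float = 0.5
    run_id: str = "sim-run"
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 1 or self.n_drugs < 1:
            raise ValueError("n_donors and n_drugs must be >= 1")
        if self.n_features < 1 or self.n_moa_classes < 1:
            raise ValueError("n_features and n_moa_classes must be >= 1")
        if not 0 < self.signature_sparsity <= 1:
            raise ValueError("signature_sparsity must lie in (0, 1]")
        if self.magnitude_sigma < 0 or self.noise_sd <= 0:
            raise ValueError("magnitude_sigma >= 0 and noise_sd > 0 required")
        if self.wells_per_condition < 1 or self.bioreplicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.dmso_wells_per_plate < 1:
            raise ValueError("each plate needs at least one DMSO well")

    @property
    def donor_ids(self) -> list[str]:
        return [f"donor{i + 1:02d}" for i in range(self.n_donors)]

    @property
    def drug_ids(self) -> list[str]:
        return [f"drug{i + 1:02d}" for i in range(self.n_drugs)]


@dataclass
class GroundTruth:
    """Planted structure of a simulated screen."""

    moa_of_drug: dict[str, int]
    signature_of_moa: np.ndarray  # (n_moa, n_features), signed, sparse
    magnitude: pd.DataFrame  # donors x MoA classes, positive scales
    responder_label: pd.DataFrame  # donors x drugs in {high, mid, low}
    duplicate_map: dict[str, str] = field(default_factory=dict)
    high_cov_features: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "moa_of_drug": self.moa_of_drug,
            "signature_of_moa": self.signature_of_moa.tolist(),
            "magnitude": self.magnitude.to_dict(),
            "responder_label": self.responder_label.to_dict(),
            "duplicate_map": self.duplicate_map,
            "high_cov_features": self.high_cov_features,
            "feature_names": self.feature_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _responder_labels(
    magnitude: pd.DataFrame,
    moa_of_drug: dict[str, int],
    quantiles: tuple[float, float],
) -> pd.DataFrame:
    """Label each (donor, drug) by the donor's magnitude quantile for the
    drug's MoA class: bottom quartile 'low', top quartile 'high', else 'mid'."""
    lo_q, hi_q = quantiles
    labels = {}
    for drug, moa in moa_of_drug.items():
        col = magnitude.iloc[:, moa]
        lo, hi = col.quantile(lo_q), col.quantile(hi_q)
        labels[drug] = np.where(col >= hi, "high", np.where(col <= lo, "low", "mid"))
    return pd.DataFrame(labels, index=magnitude.index)


def simulate_truth(config: ScreenSimConfig) -> GroundTruth:
    """Draw the planted structure (signatures, donor magnitudes, labels)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    features = [f"feat{i + 1:04d}" for i in range(config.n_features)]

    n_dup = int(round(config.frac_duplicate_features * config.n_features))
    n_dup = min(n_dup, config.n_features - 1)
    dup_idx = list(range(config.n_features - n_dup, config.n_features))
    duplicate_map = {}
    for j in dup_idx:
        src = int(rng.integers(0, config.n_features - n_dup))
        duplicate_map[features[j]] = features[src]

    indep = [i for i in range(config.n_features) if i not in set(dup_idx)]
    n_hicov = int(round(config.frac_high_cov_features * config.n_features))
    hicov_idx = rng.choice(indep, size=min(n_hicov, len(indep)), replace=False)
    high_cov_features = [features[i] for i in sorted(hicov_idx)]

    n_support = max(1, int(round(config.signature_sparsity * config.n_features)))
    sig = np.zeros((config.n_moa_classes, config.n_features))
    for m in range(config.n_moa_classes):
        support = rng.choice(indep, size=min(n_support, len(indep)), replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(support))
        mags = rng.uniform(config.effect_low, config.effect_high, size=len(support))
        sig[m, support] = signs * mags
    # duplicated features inherit their source's signature
    for j in dup_idx:
        src = features.index(duplicate_map[features[j]])
        sig[:, j] = sig[:, src]

    moa_of_drug = {
        drug: i % config.n_moa_classes for i, drug in enumerate(config.drug_ids)
    }
    mag = rng.lognormal(
        mean=0.0,
        sigma=config.magnitude_sigma,
        size=(config.n_donors, config.n_moa_classes),
    )
    if config.global_high_donor is not None:
        mag[config.global_high_donor, :] *= config.global_high_factor
    magnitude = pd.DataFrame(
        mag,
        index=config.donor_ids,
        columns=[f"moa{m}" for m in range(config.n_moa_classes)],
    )
    responder = _responder_labels(magnitude, moa_of_drug, config.responder_quantiles)
    return GroundTruth(
        moa_of_drug=moa_of_drug,
        signature_of_moa=sig,
        magnitude=magnitude,
        responder_label=responder,
        duplicate_map=duplicate_map,
        high_cov_features=high_cov_features,
        feature_names=features,
    )


def generate_screen(
    config: ScreenSimConfig,
    noise_seed: int | None = None,
) -> tuple[WellFeatureTable, GroundTruth]:
    """Simulate one assay run at well level.

    The planted structure depends only on ``config.seed``; measurement noise
    can be redrawn with ``noise_seed`` to produce replicate runs of the same
    underlying biology (used for cross-run reproducibility checks).
    """
    truth = simulate_truth(config)
    rng = np.random.default_rng(
        config.seed + 1_000_003 if noise_seed is None else noise_seed
    )
    struct_rng = np.random.default_rng(config.seed + 7)

    nf = config.n_features
    features = truth.feature_names
    baseline = struct_rng.uniform(*config.baseline_range, size=nf)
    noise_scale = config.noise_sd * np.exp(
        struct_rng.normal(0.0, config.feature_noise_sigma, size=nf)
    )
    # features meant to fail the CoV>0.5 filter: SD comparable to the mean
    hicov = np.isin(np.array(features), np.array(truth.high_cov_features))
    noise_scale[hicov] = baseline[hicov] * struct_rng.uniform(
        0.6, 1.2, size=int(hicov.sum())
    )
    dup_src = {
        features.index(f): features.index(s) for f, s in truth.duplicate_map.items()
    }

    cyto = set(config.cytotoxic_drugs)
    drugs_per_plate = (384 - config.dmso_wells_per_plate) // config.wells_per_condition
    if drugs_per_plate < 1:
        raise ValueError("plate layout leaves no room for drug wells")

    rows = []
    blocks = []
    mag = truth.magnitude
    for d_idx, donor in enumerate(config.donor_ids):
        for biorep in range(1, config.bioreplicates + 1):
            chunks = [
                config.drug_ids[i : i + drugs_per_plate]
                for i in range(0, config.n_drugs, drugs_per_plate)
            ]
            for p_idx, chunk in enumerate(chunks):
                plate = f"{donor}-b{biorep}-p{p_idx + 1}"
                plate_off = rng.normal(0.0, config.plate_sd, size=nf)
                # DMSO carrier wells first, then replicate blocks per drug
                layout = [(CONTROL_DRUG, t + 1) for t in range(config.dmso_wells_per_plate)]
                for drug in chunk:
                    layout += [
                        (drug, t + 1) for t in range(config.wells_per_condition)
                    ]
                n_wells = len(layout)
                eps = rng.normal(0.0, 1.0, size=(n_wells, nf)) * noise_scale
                vals = baseline + plate_off + eps
                for w, (drug, tech) in enumerate(layout):
                    if drug != CONTROL_DRUG:
                        m = mag.loc[donor].iloc[truth.moa_of_drug[drug]]
                        vals[w] += m * truth.signature_of_moa[truth.moa_of_drug[drug]] * noise_scale
                        if drug in cyto:
                            extra = rng.normal(0.0, 1.0, size=nf) * noise_scale
                            vals[w] += extra * np.sqrt(
                                config.cytotoxic_sd_factor**2 - 1.0
                            )
                # duplicated features copy their source up to a small jitter
                for j, s in dup_src.items():
                    vals[:, j] = vals[:, s] + rng.normal(
                        0.0, 0.02 * noise_scale[s], size=n_wells
                    )
                cells = rng.integers(
                    config.cells_per_well[0],
                    config.cells_per_well[1] + 1,
                    size=n_wells,
                )
                for w, (drug, tech) in enumerate(layout):
                    n_cells = int(cells[w])
                    if drug in cyto:
                        n_cells = int(n_cells * (1.0 - config.cytotoxic_cell_loss))
                    rows.append(
                        (
                            config.run_id,
                            plate,
                            well_name(w),
                            donor,
                            drug,
                            0.0 if drug == CONTROL_DRUG else config.dose_uM,
                            biorep,
                            tech,
                            n_cells,
                        )
                    )
                blocks.append(vals)

    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    feat = pd.DataFrame(np.vstack(blocks), columns=features)
    table = WellFeatureTable(pd.concat([meta, feat], axis=1), features, level="well")
    return table, truth


# ---------------------------------------------------------------------------
# proteome simulation
# ---------------------------------------------------------------------------

@dataclass
class ProteomeSimConfig:
    """Parameters of the simulated DIA label-free proteome.

    Defaults mirror the quantified depth of the screen's proteomics arm
    (5,895 proteins) with triplicate runs per line and condition and a
    run-to-run log2 noise SD of 0.2.
    """

    n_proteins: int = 5895
    #: number of planted drug-response proteins
    n_planted: int = 150
    #: |log2 effect| of planted proteins in a fully-responding line
    effect_range: tuple[float, float] = (1.2, 2.0)
    #: fraction of planted effects that are down-regulations
    frac_down: float = 0.5
    #: scaling of the planted effect by the line's responder label
    responder_factors: dict[str, float] = field(
        default_factory=lambda: {"high": 1.0, "mid": 0.65, "low": 0.4}
    )
    base_mean: float = 26.0  # log2 intensity
    base_sd: float = 2.5
    noise_sd: float = 0.2
    #: quantile of baseline abundance at which P(missing) = 0.5; None disables
    missing_midpoint_quantile: float | None = 0.02
    missing_steepness: float = 1.5
    seed: int = 0


@dataclass
class ProteomeTruth:
    """Planted per-protein effects: log2 shift applied in drug runs of each
    line (effect x responder factor)."""

    planted: pd.DataFrame  # index protein; columns: effect, effect_high, effect_low
    line_factor: dict[str, float]


def generate_proteome(
    config: ProteomeSimConfig,
    truth: GroundTruth | None,
    lines: list[str],
    drug: str,
    n_runs_per_condition: int = 3,
) -> tuple[ProteinQuantMatrix, ProteomeTruth]:
    """Simulate a proteins x runs intensity matrix for ``lines`` treated with
    ``drug`` or DMSO carrier, three replicate MS runs per condition each.

    When ``truth`` (from the screen simulation) is given, each line's planted
    effect is scaled by its responder label for ``drug``; without a screen
    context all lines respond fully.
    """
    rng = np.random.default_rng(config.seed)
    if truth is not None:
        known = set(truth.magnitude.index)
        unknown = [l for l in lines if l not in known]
        if unknown:
            raise ValueError(f"unknown line ids: {unknown}")
        labels = truth.responder_label[drug]
        line_factor = {
            l: config.responder_factors[str(labels.loc[l])] for l in lines
        }
    else:
        line_factor = {l: 1.0 for l in lines}

    proteins = [f"P{i + 1:05d}" for i in range(config.n_proteins)]
    base = rng.normal(config.base_mean, config.base_sd, size=config.n_proteins)

    n_planted = min(config.n_planted, config.n_proteins)
    planted_idx = rng.choice(config.n_proteins, size=n_planted, replace=False)
    effects = rng.uniform(*config.effect_range, size=n_planted)
    down = rng.random(n_planted) < config.frac_down
    effects[down] *= -1.0
    effect_vec = np.zeros(config.n_proteins)
    effect_vec[planted_idx] = effects

    run_rows = []
    cols = {}
    for line in lines:
        for treatment in (drug, CONTROL_DRUG):
            for rep in range(1, n_runs_per_condition + 1):
                run_id = f"{line}.{treatment}.r{rep}"
                run_rows.append((run_id, line, treatment, rep))
                shift = effect_vec * line_factor[line] if treatment == drug else 0.0
                cols[run_id] = base + shift + rng.normal(
                    0.0, config.noise_sd, size=config.n_proteins
                )

    intensities = pd.DataFrame(cols, index=proteins)
    if config.missing_midpoint_quantile is not None:
        midpoint = np.quantile(base, config.missing_midpoint_quantile)
        p_missing = 1.0 / (
            1.0 + np.exp(config.missing_steepness * (intensities.values - midpoint))
        )
        drop = rng.random(intensities.shape) < p_missing
        vals = intensities.values.copy()
        vals[drop] = np.nan
        intensities = pd.DataFrame(vals, index=proteins, columns=intensities.columns)

    runs = pd.DataFrame(
        run_rows, columns=["run_id", "line_id", "treatment", "replicate"]
    ).set_index("run_id")
    q = ProteinQuantMatrix(intensities=intensities, runs=runs)

    factors = np.array([line_factor[l] for l in lines])
    f_hi = float(factors.max())
    f_lo = float(factors.min())
    planted = pd.DataFrame(
        {
            "effect": effects,
            "effect_high": effects * f_hi,
            "effect_low": effects * f_lo,
        },
        index=[proteins[i] for i in planted_idx],
    )
    return q, ProteomeTruth(planted=planted, line_factor=line_factor)
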