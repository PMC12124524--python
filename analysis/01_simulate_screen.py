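"""Simulate a demonstration cohort screen and write its tables.

Generates one assay run at desk scale (8 donors x 10 drugs x 300 features,
with the assay's 6-well / 2-bioreplicate design), plus the full 28 x 52
manifest check: the three cohort designs enumerate 1,456 / 416 / 936
drug-donor pairs.
"""

from pathlib import Path

from cohortscreen import RunManifest, ScreenSimConfig, count_pairs, generate_screen
from cohortscreen.screen_data import observed_pairs

OUT = Path(__file__).resolve().parent.parent / "results" / "screen"
SEED = 2024

DEMO = ScreenSimConfig(
    n_donors=8, n_drugs=10, n_features=300, n_moa_classes=5, seed=SEED
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for n_donors in (28, 8, 18):
        manifest = RunManifest(
            run_id=f"{n_donors}-donor run",
            donors=[f"d{i}" for i in range(n_donors)],
            drugs={f"drug{i}": 5.0 for i in range(52)} | {"DMSO": 0.0},
        )
        print(f"{n_donors} donors x 52 drugs -> {count_pairs(manifest)} drug-donor pairs")

    table, truth = generate_screen(DEMO)
    table.write_csv(OUT / "features.csv")
    table.data[["plate_id", "well", "donor_id", "drug_id", "dose_uM"]].to_csv(
        OUT / "platemap.csv", index=False
    )
    truth.to_json(OUT / "ground_truth.json")
    print(
        f"\ndemo run: {table.n_rows} wells, {len(table.feature_names)} features, "
        f"{observed_pairs(table)} drug-donor pairs -> {OUT}"
    )


if __name__ == "__main__":
    main()
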