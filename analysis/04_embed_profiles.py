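"""2-D embeddings of donor-drug profiles: drugs cluster by mechanism class.

UMAP (n_neighbours 15, min_dist 0.01, cosine) and PCA coordinates of the
filtered z profiles; the silhouette of the planted MoA labels on the UMAP
plane quantifies how well mechanism classes separate.
"""

import importlib
from pathlib import Path

from sklearn.metrics import silhouette_score

from cohortscreen import aggregate, embed, normalize_and_filter
from cohortscreen.synthetic import generate_screen

sim = importlib.import_module("01_simulate_screen")
OUT = Path(__file__).resolve().parent.parent / "results" / "phenotype"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table, truth = generate_screen(sim.DEMO)
    zt, _, _ = normalize_and_filter(table)
    dd = aggregate(zt.table, "donor_drug")

    pca = embed(dd, method="pca", include_control=False)
    pca.coords.to_csv(OUT / "pca_coords.csv", index=False)
    print(
        "PCA variance explained:",
        [round(float(v), 3) for v in pca.variance_explained],
    )

    um = embed(dd, method="umap", seed=0, include_control=False)
    um.coords.to_csv(OUT / "umap_coords.csv", index=False)
    labels = [truth.moa_of_drug[g] for g in um.coords["drug_id"]]
    score = silhouette_score(um.coords[["dim1", "dim2"]].to_numpy(), labels)
    print(f"UMAP silhouette of planted MoA classes: {score:.2f}")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for ax, res, title in ((axes[0], um, "UMAP"), (axes[1], pca, "PCA")):
            ax.scatter(
                res.coords["dim1"], res.coords["dim2"],
                c=[truth.moa_of_drug[g] for g in res.coords["drug_id"]],
                cmap="tab10", s=18,
            )
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(OUT / "embeddings.png", dpi=120)
        print(f"figure -> {OUT / 'embeddings.png'}")
    except Exception as exc:  # plotting is a convenience, not a result
        print(f"skipped figure: {exc}")


if __name__ == "__main__":
    main()
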