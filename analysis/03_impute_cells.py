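"""Fill missing brood-cell counts from occupied cavity length.

Per-species OLS of cells on cavity length on nests with both quantities,
then rounded predictions for the rest; writes results/nests_imputed.csv.
"""

from pathlib import Path

from matchdem.brood import impute_cells
from matchdem.io_formats import read_nests, write_nests

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    nests = read_nests(ROOT / "data" / "nests.csv")
    full, models = impute_cells(nests)
    write_nests(full, ROOT / "nests_imputed.csv")
    for taxon, model in models.items():
        n_imputed = int(full.loc[full["bee_taxon"] == taxon, "estimated"].sum())
        print(
            f"{taxon}: cells = {model.intercept:.2f} + {model.slope:.4f}/mm, "
            f"r2 = {model.r_squared:.3f} (trained on {model.n_train}, "
            f"imputed {n_imputed})"
        )


if __name__ == "__main__":
    main()
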