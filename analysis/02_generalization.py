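"""Score each bee species' diet breadth from its nest pollen contents.

Shannon H of summed per-nest pollen proportions; writes
results/generalization.csv and prints the specialization ranking.
"""

from pathlib import Path

import pandas as pd

from matchdem.generalization import generalization_scores
from matchdem.io_formats import read_nests, read_pollen

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    nests = read_nests(ROOT / "data" / "nests.csv")
    pollen = read_pollen(ROOT / "data" / "pollen.csv")
    scores = generalization_scores(pollen, nests)
    df = pd.DataFrame(
        [
            {"bee_taxon": t, "shannon_h": s.shannon_h, "n_nests": s.n_nests}
            for t, s in sorted(scores.items(), key=lambda kv: kv[1].shannon_h)
        ]
    )
    df.to_csv(ROOT / "generalization.csv", index=False)
    print("diet breadth, most specialized first:")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
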