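"""Generate the study dataset: 9 seasons, 2 sites, 5 bee species.

Writes the three field tables (floral surveys, nest records, pollen
samples) for the default scenario under results/data/.
"""

from pathlib import Path

from matchdem.io_formats import write_floral_surveys, write_nests, write_pollen
from matchdem.simulate import default_scenario, generate_dataset

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_scenario(seed=SEED)
    flowers, nests, pollen = generate_dataset(cfg, seed=SEED)
    write_floral_surveys(flowers, OUT / "flowers.csv")
    write_nests(nests, OUT / "nests.csv")
    write_pollen(pollen, OUT / "pollen.csv")
    print(f"{len(nests)} nests over {nests['season_year'].nunique()} seasons, "
          f"{nests['bee_taxon'].nunique()} bee species")
    print(nests.groupby("bee_taxon").size().to_string())
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
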