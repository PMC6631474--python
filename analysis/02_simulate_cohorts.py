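"""Simulate the two paired-platform study cohorts with known ground truth.

Generates a deep multi-timepoint cohort (4 subjects × 56 timepoints with
baseline/intervention pairs around three lipid-related challenges) and a
wide cross-sectional cohort (305 subjects with sex and diabetes-group
labels), both observed by a species-level kit platform and a side-chain
resolving platform.  True constituent proportions come from the packaged
reference composition table, so every downstream estimate has a known
target.  Writes the concentration tables and the expected ratios under
results/synthetic/.
"""

from pathlib import Path

import pandas as pd

from pccomp import (
    default_humet_config,
    default_qmdiab_config,
    load_reference,
    simulate_paired_cohort,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20190608


def write_cohort(name: str, config) -> None:
    species, fa, truth = simulate_paired_cohort(config)
    out = OUT / name
    out.mkdir(parents=True, exist_ok=True)
    species.write(out / "species_level.tsv")
    fa.write(out / "fatty_acid_level.tsv")
    expected = pd.DataFrame(
        [
            {"sum_label": i, "constituent_label": j, "expected_q": q}
            for (i, j), q in truth.expected_q.items()
        ]
    )
    expected.to_csv(out / "expected_q.tsv", sep="\t", index=False)
    print(
        f"{name}: {len(species.sample_ids)} samples, "
        f"{len(species.analytes)} sums, {len(fa.analytes)} constituents "
        f"-> {out}"
    )


def main() -> None:
    table = load_reference()
    write_cohort("deep", default_humet_config(table, seed=SEED))
    write_cohort("cross_sectional", default_qmdiab_config(table, seed=SEED + 1))


if __name__ == "__main__":
    main()
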