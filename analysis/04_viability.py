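"""Egg viability: host eclosion and parasitoid emergence per treatment cell.

Clutch-weighted binomial logits with Tukey letter displays; boundary cells
(no successes at all) are reported with rule-of-three intervals and enter
the letters through a flagged continuity-corrected refit.
"""

import argparse
from pathlib import Path

import pandas as pd

from parayield import io
from parayield.design import HOST_ECLOSION, PARASITOID_EMERGENCE
from parayield.posthoc import tukey_pairs
from parayield.proportions import build_binomial_sample, emm_props, fit_weighted_logit


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--clutches", type=Path, default=Path("results/data/clutches.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/viability"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    clutches = io.read_clutches(args.clutches)

    for outcome in (HOST_ECLOSION, PARASITOID_EMERGENCE):
        sample = build_binomial_sample(clutches, outcome)
        fit = fit_weighted_logit(sample)
        letter_fit = fit_weighted_logit(sample, continuity=True) if fit.boundary_cells else fit
        emm = emm_props(fit)
        letters = tukey_pairs(emm_props(letter_fit)).letters
        frame = emm.to_frame()
        frame["percent"] = (100 * frame["estimate"]).round(2)
        frame["eggs"] = [int(fit.cell_eggs.get(c, 0)) for c in frame["cell"]]
        frame["letter"] = [letters.get(c, "") for c in frame["cell"]]
        frame.insert(0, "outcome", outcome)
        frame.to_csv(args.out / f"{outcome}.csv", index=False)
        print(f"\n{outcome} ({fit.n_clutches} clutches, {fit.n_eggs} eggs"
              + (f"; boundary cells {fit.boundary_cells}" if fit.boundary_cells else "") + ")")
        print(frame[["cell", "eggs", "percent", "letter", "note"]].to_string(index=False))


if __name__ == "__main__":
    main()
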