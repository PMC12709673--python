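#!/usr/bin/env python
"""Build S-binding sequence logos and compare 1- vs 2-binding information.

For every nonempty S-class with |S| in {1, 2} (up to 7 + 21 = 28 classes) a
position frequency matrix with per-position information content is computed.
Cross-reactive (2-binding) classes concentrate on the shared alpha-chain
motif, so their logos carry more information at the alpha positions than
target-specific (1-binding) logos.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from kbinding.binding_analysis import logo_grid
from kbinding.synthetic_data import DEFAULT_TARGETS


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    out = Path(args.outdir)

    profiles = pd.read_csv(out / "profiles.tsv", sep="\t",
                           dtype={"cdr3_alpha": str, "cdr3_beta": str})
    grid = logo_grid(profiles, DEFAULT_TARGETS)

    rows = []
    for S, logo in sorted(grid.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        for pos in logo.info.index:
            rows.append({"S": "+".join(sorted(S)), "k": len(S), "position": pos,
                         "information_bits": logo.info[pos],
                         "n_sequences": logo.n_sequences})
    info = pd.DataFrame(rows)
    info.to_csv(out / "logo_information.tsv", sep="\t", index=False)

    alpha_pos = ["a99", "a100", "a101"]
    ic = (info[info["position"].isin(alpha_pos)]
          .groupby("k")["information_bits"].mean())
    print(f"{len(grid)} nonempty S-classes (max 28)")
    print(f"mean alpha-position information: 1-binding {ic.get(1, np.nan):.2f} bits, "
          f"2-binding {ic.get(2, np.nan):.2f} bits")
    print("2-binding logos are richer at the shared motif:", bool(ic.get(2, 0) > ic.get(1, 0)))


if __name__ == "__main__":
    main()
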