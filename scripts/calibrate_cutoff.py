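"""One-time calibration of the default punctate/diffuse enrichment cutoff.

Runs the synthetic punctate (diffuse_fraction 0) and diffuse
(diffuse_fraction 0.9) generators at their default study conditions,
computes % ΔF/F for each trace, and prints the midpoint of the two label
means.  The result is frozen into ``synaptoquant.config.DEFAULT_CUTOFF_PCT``.

Usage: python scripts/calibrate_cutoff.py [--n-seeds 200]
"""

import argparse

import numpy as np

from synaptoquant.linescan import find_extrema, synaptic_enrichment
from synaptoquant.synthetic import LineScanParams, gen_linescan


def label_mean(diffuse_fraction: float, n_seeds: int) -> np.ndarray:
    vals = []
    for seed in range(n_seeds):
        profile, _ = gen_linescan(LineScanParams(diffuse_fraction=diffuse_fraction, seed=seed))
        enr = synaptic_enrichment(find_extrema(profile), cutoff_percent=1.0)
        vals.append(enr.delta_f_over_f_percent)
    return np.array(vals)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-seeds", type=int, default=200)
    args = ap.parse_args()
    punctate = label_mean(0.0, args.n_seeds)
    diffuse = label_mean(0.9, args.n_seeds)
    mid = (punctate.mean() + diffuse.mean()) / 2.0
    print(f"punctate: mean {punctate.mean():.1f}%  range [{punctate.min():.1f}, {punctate.max():.1f}]")
    print(f"diffuse:  mean {diffuse.mean():.1f}%  range [{diffuse.min():.1f}, {diffuse.max():.1f}]")
    print(f"midpoint cutoff: {mid:.1f}%")


if __name__ == "__main__":
    main()
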