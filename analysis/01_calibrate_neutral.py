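#!/usr/bin/env python
"""Neutral calibration of the forward locus engine.

Simulates constant-size neutral loci (msprime equilibrium start, forward
Wright-Fisher continuation), then checks that the sampled Watterson estimator
is unbiased for the input theta, that Tajima's D is centred on zero, and that
Hudson's FST between random halves of a panmictic sample is centred on zero.
Writes results/neutral_calibration.json.
"""

import argparse
import json
import pathlib
from dataclasses import replace

import numpy as np

from sweepscan import simulate as sim
from sweepscan import sumstats as ss
from sweepscan.popdata import PopulationPair


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-loci", type=int, default=200)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    N, u_locus, r_locus, L = 200, 0.01, 0.05, 105_000
    theta_in = 4 * N * u_locus

    thetas, tds = [], []
    for _ in range(args.n_loci):
        hap = sim.simulate_constant_locus(N, 40, u_locus, r_locus, 60, L, rng)
        thetas.append(ss.watterson_theta(hap, None, L) * L)
        tds.append(ss.tajimas_d(hap))
    thetas = np.asarray(thetas)
    tds = np.asarray(tds)

    # panmictic sample split at random into two pseudo-populations
    big = sim.simulate_constant_locus(400, 80, 0.02, 0.05, 60, L, rng)
    fsts = []
    for _ in range(100):
        pops = np.array(["X"] * 40)
        pops[rng.permutation(40)[:20]] = "Y"
        relabeled = replace(big, pop_of_sample=pops)
        fsts.append(ss.hudson_fst(relabeled, None, PopulationPair("X", "Y", 40, 40)))

    out = {
        "theta_input": theta_in,
        "theta_hat_mean": float(thetas.mean()),
        "theta_hat_se": float(thetas.std(ddof=1) / np.sqrt(len(thetas))),
        "tajimas_d_mean": float(np.nanmean(tds)),
        "tajimas_d_se": float(np.nanstd(tds, ddof=1) / np.sqrt(len(tds))),
        "panmictic_split_fst_mean": float(np.mean(fsts)),
        "n_loci": args.n_loci,
    }
    outdir = pathlib.Path(args.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "neutral_calibration.json").write_text(json.dumps(out, indent=2))
    print(
        f"theta_hat {out['theta_hat_mean']:.2f} (input {theta_in:.2f}, "
        f"SE {out['theta_hat_se']:.2f}); Tajima's D {out['tajimas_d_mean']:+.3f}; "
        f"panmictic FST {out['panmictic_split_fst_mean']:+.5f}"
    )


if __name__ == "__main__":
    main()
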