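#!/usr/bin/env python
"""Windowed Hudson-FST tracks and the unfolded 2D site-frequency spectrum.

Runs the differentiation side of the pipeline on a synthetic cohort read
back from its files (VCF + popfile + BED mask + depths), exactly as an
empirical cohort would be: coverage filter, mask, 10-kb ratio-of-averages
FST windows with the valid-site rule, loess smoothing, and the 40-allele
downsampled 2D SFS after outgroup polarization.  Writes
results/fst_track_<chrom>.tsv and results/sfs2d.tsv; a Manhattan-style plot
and an SFS heatmap go to scratch/plots/ when matplotlib is available.
"""

import argparse
import json
import pathlib
import tempfile

import numpy as np

from sweepscan import simulate as sim
from sweepscan import synthfix as sf
from sweepscan.popdata import (
    GenotypeDepthMatrix,
    PopulationPair,
    SiteMask,
    polarize,
    read_phased_vcf,
    read_popfile,
)
from sweepscan.scans import build_2dsfs, loess_smooth, window_fst_scan


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--fixture-dir", default=None, help="reuse an existing cohort")
    args = ap.parse_args()

    model, prof = sim.desk_model(), sim.desk_profile()
    spec = sf.FixtureSpec(
        n_chroms=2, chrom_bp=2_000_000, model=model, profile=prof,
        planted=[("chr1", 800_000, "divergent", 0.1, "de_novo")],
        masked_fraction=0.38, seed=args.seed,
        depth_model=(25.0, 5.0, 0.05),
    )
    workdir = args.fixture_dir or tempfile.mkdtemp()
    cohort = sf.make_cohort(spec, workdir)

    popfile = read_popfile(cohort.paths["popfile"])
    outdir = pathlib.Path(args.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    pair = PopulationPair("A", "B", 40, 40)

    sfs_rows = []
    summary = {}
    for chrom in spec.chrom_names():
        hap = read_phased_vcf(cohort.paths["cohort_vcf"][chrom], popfile)
        og = read_phased_vcf(cohort.paths["outgroup_vcf"][chrom], popfile)
        hap = polarize(hap, og)
        mask = SiteMask.from_bed(cohort.paths["mask_bed"], chrom, spec.chrom_bp)
        depth = GenotypeDepthMatrix(
            np.loadtxt(cohort.paths["depths"][chrom], dtype=int, delimiter="\t")
        )
        track = window_fst_scan(hap, mask, depth, pair, 10_000, 2_000)
        loess_smooth(track, span=max(0.01, 10 / max(len(track.windows), 1)))
        track.to_tsv(outdir / f"fst_track_{chrom}.tsv")
        summary[chrom] = {
            "n_windows": int(len(track.windows)),
            "median_fst": float(track.windows["fst"].median()),
            "max_fst": float(track.windows["fst"].max()),
        }
        sfs = build_2dsfs(hap, pair, 40, 40, seed=args.seed)
        sfs_rows.append(sfs)

    total = sfs_rows[0].counts + sfs_rows[1].counts
    np.savetxt(outdir / "sfs2d.tsv", total, fmt="%d", delimiter="\t")
    summary["sfs2d_total_sites"] = int(total.sum())
    (outdir / "fst_sfs_summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plots = pathlib.Path("scratch/plots")
        plots.mkdir(parents=True, exist_ok=True)
        fig, axes = plt.subplots(2, 1, figsize=(10, 5), sharey=True)
        for ax, chrom in zip(axes, spec.chrom_names()):
            hap = read_phased_vcf(cohort.paths["cohort_vcf"][chrom], popfile)
            mask = SiteMask.from_bed(cohort.paths["mask_bed"], chrom, spec.chrom_bp)
            track = window_fst_scan(hap, mask, None, pair, 10_000, 2_000)
            mid = (track.windows["start"] + track.windows["end"]) / 2
            ax.plot(mid / 1e6, track.windows["fst"], ".", ms=3, color="grey")
            sm = loess_smooth(track, span=0.1)
            ax.plot(mid / 1e6, sm, color="crimson")
            ax.set_ylabel(f"{chrom} $F_{{ST}}$")
        axes[-1].set_xlabel("position (Mb)")
        fig.tight_layout()
        fig.savefig(plots / "fst_manhattan.png", dpi=150)

        fig2, ax2 = plt.subplots(figsize=(5, 4.5))
        with np.errstate(divide="ignore"):
            ax2.imshow(np.log10(total.T + 0.5), origin="lower", cmap="viridis")
        ax2.set_xlabel("derived count, population A")
        ax2.set_ylabel("derived count, population B")
        fig2.tight_layout()
        fig2.savefig(plots / "sfs2d_heatmap.png", dpi=150)
    except ImportError:
        pass


if __name__ == "__main__":
    main()
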