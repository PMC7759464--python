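"""End-to-end synthetic fixtures emulating the study's empirical inputs.

:func:`make_cohort` writes a complete small cohort — phased two-population
VCFs, an outgroup VCF for polarization, a BED accessibility mask with a
realistic masked fraction, a popfile, per-site depths and a ground-truth BED
of planted sweep loci — generated from the same demographic model the
simulator uses: msprime supplies the neutral multi-chromosome background
(with a deeply diverged outgroup lineage), and planted shared/divergent
sweep loci from :func:`sweepscan.simulate.simulate_instance` are spliced in
at the requested positions.  Everything is reproducible byte-for-byte from
the recipe's seed.

Fixture realism has limits that matter for interpretation: haplotypes are
spliced at planted-locus boundaries without LD continuity, outgroup
genotypes inside planted loci are all-ancestral, and REF/ALT coding is
randomized per site so the polarization rule is actually exercised.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .popdata import (
    DemographicModel,
    GenotypeDepthMatrix,
    HaplotypeMatrix,
    SiteMask,
)
from .simulate import (
    ScaleProfile,
    _matrix_from_ts,
    demography_for,
    desk_model,
    desk_profile,
    draw_sim_params,
    simulate_instance,
)

__all__ = ["FixtureSpec", "Cohort", "make_cohort", "make_depths", "random_mask"]


@dataclass
class FixtureSpec:
    """Recipe for one synthetic cohort.

    ``planted`` lists (chrom, position, category, s, origin) sweep loci;
    planted positions must sit inside their chromosome and at least one
    locus length apart.  ``depth_model`` is (mean, dispersion,
    fail_fraction): negative-binomial sequencing depths with a fraction of
    sites engineered to fail the 80%-at-5x rule.
    """

    n_chroms: int = 2
    chrom_bp: int = 2_000_000
    model: DemographicModel = field(default_factory=desk_model)
    profile: ScaleProfile = field(default_factory=desk_profile)
    planted: list = field(default_factory=list)
    masked_fraction: float = 0.38
    outgroup_n: int = 5
    n_a: int = 40  # haplotypes (20 diploids)
    n_b: int = 40
    pair_labels: tuple[str, str] = ("A", "B")
    outgroup_split_factor: float = 12.0
    depth_model: tuple[float, float, float] = (25.0, 5.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.masked_fraction <= 0.9:
            raise ValueError("masked_fraction must be in [0, 0.9]")
        L = self.profile.locus_bp
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos, category, s, origin in self.planted:
            if category not in ("shared", "divergent"):
                raise ValueError(f"planted category must be shared/divergent, got {category!r}")
            if origin not in ("de_novo", "standing"):
                raise ValueError(f"unknown origin {origin!r}")
            if pos < 0 or pos + L > self.chrom_bp:
                raise ValueError(f"planted locus at {chrom}:{pos} exceeds the chromosome")
            by_chrom.setdefault(chrom, []).append(int(pos))
        for chrom, positions in by_chrom.items():
            positions.sort()
            for a, b in zip(positions, positions[1:]):
                if b - a < L:
                    raise ValueError(f"planted loci on {chrom} closer than one locus length")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class Cohort:
    """In-memory ground truth of a written fixture set."""

    spec: FixtureSpec
    haps: dict[str, HaplotypeMatrix]
    outgroups: dict[str, HaplotypeMatrix]
    masks: dict[str, SiteMask]
    depths: dict[str, GenotypeDepthMatrix]
    truth: list  # (chrom, start, end, category)
    paths: dict


def _simulate_background(
    spec: FixtureSpec, chrom: str, rng: np.random.Generator
) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    """Neutral ingroup + outgroup background for one chromosome, sharing one
    coordinate system (a single msprime run)."""
    import msprime

    model = spec.model
    prof = spec.profile
    a, b = spec.pair_labels
    dem = demography_for(
        model,
        spec.pair_labels,
        outgroup_split_time=int(spec.outgroup_split_factor * model.colonization_time),
        outgroup_size=model.ancestral_size,
    )
    seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples={a: spec.n_a // 2, b: spec.n_b // 2, "OUT": spec.outgroup_n},
        demography=dem,
        sequence_length=spec.chrom_bp,
        recombination_rate=model.recombination_rate * prof.recombination_scale,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=model.mutation_rate * prof.mutation_scale,
        random_seed=seed + 1,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
    )
    joint = _matrix_from_ts(
        mts,
        chrom,
        [(a, spec.n_a // 2), (b, spec.n_b // 2), ("OUT", spec.outgroup_n)],
    )
    n_in = spec.n_a + spec.n_b
    ing_rows = np.arange(n_in)
    out_rows = np.arange(n_in, n_in + 2 * spec.outgroup_n)
    # keep sites polymorphic within the ingroup; outgroup stays aligned
    ing_alleles = joint.alleles[ing_rows]
    tot = ing_alleles.sum(axis=0, dtype=np.int64)
    seg = np.flatnonzero((tot > 0) & (tot < n_in))
    ingroup = HaplotypeMatrix(
        ing_alleles[:, seg],
        joint.positions[seg],
        chrom,
        joint.sample_ids[: n_in // 2],
        joint.pop_of_sample[: n_in // 2],
        np.ones(seg.size, dtype=bool),
    )
    outgroup = HaplotypeMatrix(
        joint.alleles[out_rows][:, seg],
        joint.positions[seg],
        chrom,
        joint.sample_ids[n_in // 2 :],
        joint.pop_of_sample[n_in // 2 :],
        np.ones(seg.size, dtype=bool),
    )
    return ingroup, outgroup


def _splice_locus(
    background: HaplotypeMatrix,
    outgroup: HaplotypeMatrix,
    inst_hap: HaplotypeMatrix,
    offset: int,
    locus_bp: int,
) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    """Replace background variation in [offset, offset+locus_bp) with the
    planted instance's columns (outgroup all-ancestral there)."""
    keep = (background.positions < offset) | (background.positions >= offset + locus_bp)
    keep_idx = np.flatnonzero(keep)
    new_pos = inst_hap.positions + offset
    alleles = np.concatenate(
        [background.alleles[:, keep_idx], inst_hap.alleles], axis=1
    )
    og_alleles = np.concatenate(
        [outgroup.alleles[:, keep_idx], np.zeros((outgroup.n_haplotypes, new_pos.size), np.int8)],
        axis=1,
    )
    pos = np.concatenate([background.positions[keep_idx], new_pos])
    order = np.argsort(pos, kind="stable")
    bg = HaplotypeMatrix(
        alleles[:, order],
        pos[order],
        background.chrom,
        background.sample_ids,
        background.pop_of_sample,
        np.ones(pos.size, dtype=bool),
    )
    og = HaplotypeMatrix(
        og_alleles[:, order],
        pos[order],
        outgroup.chrom,
        outgroup.sample_ids,
        outgroup.pop_of_sample,
        np.ones(pos.size, dtype=bool),
    )
    return bg, og


def random_mask(
    chrom: str, length: int, target_fraction: float, rng: np.random.Generator,
    mean_interval: float = 800.0,
) -> SiteMask:
    """Random masked intervals (exponential lengths) accumulated until the
    realized masked fraction reaches the target."""
    if target_fraction <= 0:
        return SiteMask(chrom, length)
    masked = np.zeros(length, dtype=bool)
    target_bp = int(target_fraction * length)
    while masked.sum() < target_bp:
        l = max(1, int(rng.exponential(mean_interval)))
        s = int(rng.integers(0, length))
        masked[s : min(s + l, length)] = True
    return SiteMask.from_boolean(chrom, masked)


def make_depths(
    n_samples: int,
    n_sites: int,
    rng: np.random.Generator,
    mean: float = 25.0,
    dispersion: float = 5.0,
    fail_fraction: float = 0.0,
    min_depth: int = 5,
    min_frac: float = 0.8,
) -> GenotypeDepthMatrix:
    """Negative-binomial synthetic depths; a ``fail_fraction`` of sites is
    engineered to fail the >=``min_depth``x in >=``min_frac`` rule by zeroing
    depths for just over 1-min_frac of the individuals."""
    if mean <= min_depth:
        import warnings

        warnings.warn(
            "mean depth <= min_depth: the all-pass regime is unattainable",
            stacklevel=2,
        )
    p = dispersion / (dispersion + mean)
    depth = rng.negative_binomial(dispersion, p, size=(n_samples, n_sites))
    depth = np.maximum(depth, min_depth)  # background sites always pass
    if fail_fraction > 0:
        n_fail = int(round(fail_fraction * n_sites))
        fail_sites = rng.choice(n_sites, size=n_fail, replace=False)
        # enough low-depth individuals that the passing share falls strictly
        # below min_frac
        n_low = n_samples - int(np.ceil(min_frac * n_samples - 1e-9)) + 1
        for j in fail_sites:
            rows = rng.choice(n_samples, size=n_low, replace=False)
            depth[rows, j] = 0
    return GenotypeDepthMatrix(depth)


def _write_flipped_vcf(
    hap: HaplotypeMatrix, flip: np.ndarray, path, phased: bool = True
) -> None:
    """VCF with REF/ALT coding flipped at the flagged sites (REF is then the
    derived base), exercising the polarization step on read-back."""
    from .popdata import MISSING

    sep = "|" if phased else "/"
    allele_str = {0: "0", 1: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        length = int(hap.positions[-1]) + 1 if hap.n_sites else 1
        fh.write(f"##contig=<ID={hap.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(hap.sample_ids) + "\n")
        for j in range(hap.n_sites):
            ref, alt = ("T", "A") if flip[j] else ("A", "T")
            col = hap.alleles[:, j]
            if flip[j]:
                col = np.where(col == MISSING, MISSING, 1 - col)
            body = "\t".join(
                f"{allele_str[int(col[2 * i])]}{sep}{allele_str[int(col[2 * i + 1])]}"
                for i in range(hap.n_samples)
            )
            fh.write(f"{hap.chrom}\t{hap.positions[j] + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{body}\n")


def make_cohort(spec: FixtureSpec, outdir: str) -> Cohort:
    """Write the full fixture file set and return the in-memory ground truth.

    Files per chromosome: ``cohort_<chrom>.vcf`` (phased ingroup),
    ``outgroup_<chrom>.vcf``, ``depths_<chrom>.tsv``; plus ``mask.bed``,
    ``popfile.tsv``, ``truth.bed`` and ``manifest.json``.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    L = spec.profile.locus_bp
    a, b = spec.pair_labels

    haps: dict[str, HaplotypeMatrix] = {}
    outgroups: dict[str, HaplotypeMatrix] = {}
    masks: dict[str, SiteMask] = {}
    depths: dict[str, GenotypeDepthMatrix] = {}
    truth: list = []
    planted_params: list[dict] = []

    for chrom in spec.chrom_names():
        ingroup, outgroup = _simulate_background(spec, chrom, rng)
        for p_chrom, pos, category, s, origin in spec.planted:
            if p_chrom != chrom:
                continue
            params = draw_sim_params(category, origin, spec.model, rng, L)
            params = dc_replace(params, s=float(s))
            inst = simulate_instance(
                params,
                spec.model,
                spec.n_a,
                spec.n_b,
                np.random.default_rng(params.seed),
                spec.profile,
                spec.pair_labels,
                chrom,
            )
            ingroup, outgroup = _splice_locus(ingroup, outgroup, inst.hap, int(pos), L)
            truth.append((chrom, int(pos), int(pos) + L, category))
            planted_params.append(
                {"chrom": chrom, "pos": int(pos), "category": category,
                 "seed": params.seed, "s": float(s), "origin": origin,
                 "swept": inst.meta.get("swept")}
            )
        masks[chrom] = random_mask(chrom, spec.chrom_bp, spec.masked_fraction, rng)
        mean, disp, fail = spec.depth_model
        depths[chrom] = make_depths(
            ingroup.n_samples, ingroup.n_sites, rng, mean, disp, fail
        )
        haps[chrom] = ingroup
        outgroups[chrom] = outgroup

    paths: dict = {"cohort_vcf": {}, "outgroup_vcf": {}, "depths": {}}
    for chrom in spec.chrom_names():
        flip = rng.random(haps[chrom].n_sites) < 0.5
        cohort_path = os.path.join(outdir, f"cohort_{chrom}.vcf")
        out_path = os.path.join(outdir, f"outgroup_{chrom}.vcf")
        _write_flipped_vcf(haps[chrom], flip, cohort_path, phased=True)
        _write_flipped_vcf(outgroups[chrom], flip, out_path, phased=True)
        paths["cohort_vcf"][chrom] = cohort_path
        paths["outgroup_vcf"][chrom] = out_path
        depth_path = os.path.join(outdir, f"depths_{chrom}.tsv")
        np.savetxt(depth_path, depths[chrom].depth, fmt="%d", delimiter="\t")
        paths["depths"][chrom] = depth_path

    mask_path = os.path.join(outdir, "mask.bed")
    with open(mask_path, "w") as fh:
        pass
    for chrom in spec.chrom_names():
        masks[chrom].to_bed(mask_path, mode="a")
    paths["mask_bed"] = mask_path

    pop_path = os.path.join(outdir, "popfile.tsv")
    with open(pop_path, "w") as fh:
        fh.write("# sample\tpopulation\n")
        some = haps[spec.chrom_names()[0]]
        for sid, pop in zip(some.sample_ids, some.pop_of_sample):
            fh.write(f"{sid}\t{pop}\n")
        for i in range(spec.outgroup_n):
            fh.write(f"OUT_{i}\tOUT\n")
    paths["popfile"] = pop_path

    truth_path = os.path.join(outdir, "truth.bed")
    with open(truth_path, "w") as fh:
        for chrom, s_, e_, category in truth:
            fh.write(f"{chrom}\t{s_}\t{e_}\t{category}\n")
    paths["truth_bed"] = truth_path

    manifest = {
        "seed": spec.seed,
        "n_chroms": spec.n_chroms,
        "chrom_bp": spec.chrom_bp,
        "masked_fraction_target": spec.masked_fraction,
        "masked_fraction_realized": {
            c: masks[c].masked_fraction() for c in spec.chrom_names()
        },
        "planted": planted_params,
        "pair": [a, b],
        "n_haplotypes": [spec.n_a, spec.n_b],
        "outgroup_n": spec.outgroup_n,
    }
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = manifest_path

    return Cohort(spec, haps, outgroups, masks, depths, truth, paths)
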