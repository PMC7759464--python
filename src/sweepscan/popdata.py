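"""Domain types and I/O for phased two-population cohorts.

Everything downstream (summary statistics, feature matrices, scans) operates
on a :class:`HaplotypeMatrix`: a haplotypes x sites matrix of 0/1 alleles with
0-based positions, per-sample population labels and a per-site polarization
flag (0 = ancestral once polarized against an outgroup).  Accessibility is
carried separately as a :class:`SiteMask` of masked intervals.

Coordinates are 0-based half-open everywhere inside the package; the 1-based
convention appears only at the VCF boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "HaplotypeMatrix",
    "SiteMask",
    "PopulationPair",
    "DemographicModel",
    "GenotypeDepthMatrix",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_popfile",
    "read_demographic_model",
    "polarize",
    "apply_mask",
    "coverage_filter",
]


# ---------------------------------------------------------------------------
# types


@dataclass
class HaplotypeMatrix:
    """Phased allele matrix: rows = haplotypes (two consecutive per sample),
    columns = biallelic polymorphic sites.

    ``alleles`` holds 0 (reference/ancestral), 1 (alternate/derived) or
    :data:`MISSING`.  ``positions`` are 0-based and strictly increasing.
    ``polarized`` flags sites whose 0/1 coding is known to mean
    ancestral/derived (set by :func:`polarize`, or by construction for
    simulated data).
    """

    alleles: np.ndarray
    positions: np.ndarray
    chrom: str
    sample_ids: list[str]
    pop_of_sample: np.ndarray
    polarized: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.pop_of_sample = np.asarray(self.pop_of_sample)
        self.polarized = np.asarray(self.polarized, dtype=bool)
        n_hap, n_sites = self.alleles.shape
        if n_hap % 2 != 0:
            raise ValueError("haplotype count must be even (two per diploid)")
        if len(self.sample_ids) != n_hap // 2:
            raise ValueError("sample_ids length must equal half the row count")
        if len(self.pop_of_sample) != len(self.sample_ids):
            raise ValueError("pop_of_sample must have one label per sample")
        if self.positions.shape != (n_sites,):
            raise ValueError("positions length must equal the column count")
        if n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.polarized.shape != (n_sites,):
            raise ValueError("polarized flag must have one entry per site")
        ok = (self.alleles == 0) | (self.alleles == 1) | (self.alleles == MISSING)
        if not ok.all():
            raise ValueError("alleles must be 0, 1 or MISSING")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.pop_of_sample:
            if p not in seen:
                seen.append(str(p))
        return seen

    def sample_rows(self, sample_index: int) -> tuple[int, int]:
        return 2 * sample_index, 2 * sample_index + 1

    def rows_for_pop(self, pop: str) -> np.ndarray:
        """Haplotype row indices belonging to population ``pop``."""
        samples = np.flatnonzero(self.pop_of_sample == pop)
        if samples.size == 0:
            raise KeyError(f"no samples labelled {pop!r}")
        return np.repeat(2 * samples, 2) + np.tile([0, 1], samples.size)

    def subpop(self, pop: str) -> "HaplotypeMatrix":
        samples = np.flatnonzero(self.pop_of_sample == pop)
        rows = self.rows_for_pop(pop)
        return HaplotypeMatrix(
            self.alleles[rows],
            self.positions,
            self.chrom,
            [self.sample_ids[i] for i in samples],
            self.pop_of_sample[samples],
            self.polarized,
        )

    def take_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            alleles=self.alleles[:, idx],
            positions=self.positions[idx],
            polarized=self.polarized[idx],
        )

    def restrict(self, start: int, end: int) -> "HaplotypeMatrix":
        """Sites with position in the half-open interval [start, end)."""
        lo = np.searchsorted(self.positions, start, side="left")
        hi = np.searchsorted(self.positions, end, side="left")
        return self.take_sites(np.arange(lo, hi))


@dataclass
class SiteMask:
    """Per-base accessibility track: a set of masked half-open intervals."""

    chrom: str
    length: int
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ends: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        if starts.shape != ends.shape:
            raise ValueError("starts and ends must have equal length")
        if np.any(starts < 0) or np.any(ends > self.length) or np.any(ends < starts):
            raise ValueError("mask intervals must lie within [0, length)")
        # normalize: sort and merge overlapping/adjacent intervals
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        ms, me = [], []
        for s, e in zip(starts, ends):
            if e == s:
                continue
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        self.starts = np.asarray(ms, dtype=np.int64)
        self.ends = np.asarray(me, dtype=np.int64)

    @classmethod
    def from_intervals(cls, chrom: str, length: int, intervals: Iterable[tuple[int, int]]) -> "SiteMask":
        ivs = list(intervals)
        starts = [s for s, _ in ivs]
        ends = [e for _, e in ivs]
        return cls(chrom, length, np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64))

    @classmethod
    def from_bed(cls, path, chrom: str, length: int) -> "SiteMask":
        """Masked intervals for ``chrom`` from a 0-based half-open BED file."""
        starts, ends = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if parts[0] != chrom:
                    continue
                starts.append(int(parts[1]))
                ends.append(int(parts[2]))
        return cls(chrom, length, np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64))

    @classmethod
    def from_fasta(cls, path, chrom: str, dialect: str = "N") -> "SiteMask":
        """Mask from a hard-masked FASTA: ``dialect`` 'N' treats N/n as masked,
        'lowercase' treats lowercase letters as masked, 'both' either."""
        seq = None
        name = None
        chunks: list[str] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith(">"):
                    if name == chrom:
                        break
                    name = line[1:].split()[0]
                    chunks = []
                elif name == chrom:
                    chunks.append(line.strip())
        if name != chrom and not chunks:
            raise KeyError(f"chromosome {chrom!r} not found in {path}")
        seq = "".join(chunks)
        arr = np.frombuffer(seq.encode(), dtype="S1")
        if dialect == "N":
            masked = (arr == b"N") | (arr == b"n")
        elif dialect == "lowercase":
            masked = np.char.islower(arr.astype("U1"))
        elif dialect == "both":
            masked = (arr == b"N") | (arr == b"n") | np.char.islower(arr.astype("U1"))
        else:
            raise ValueError(f"unknown FASTA mask dialect {dialect!r}")
        return cls.from_boolean(chrom, masked)

    @classmethod
    def from_boolean(cls, chrom: str, masked: np.ndarray) -> "SiteMask":
        masked = np.asarray(masked, dtype=bool)
        padded = np.concatenate([[False], masked, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        return cls(chrom, masked.size, starts.astype(np.int64), ends.astype(np.int64))

    # -- queries ------------------------------------------------------------

    def masked_bp(self, start: int = 0, end: int | None = None) -> int:
        """Masked base pairs overlapping the half-open query interval."""
        if end is None:
            end = self.length
        if self.starts.size == 0 or end <= start:
            return 0
        s = np.clip(self.starts, start, end)
        e = np.clip(self.ends, start, end)
        return int(np.maximum(e - s, 0).sum())

    def accessible_bp(self, start: int = 0, end: int | None = None) -> int:
        if end is None:
            end = self.length
        return max(end - start, 0) - self.masked_bp(start, end)

    def masked_fraction(self) -> float:
        return self.masked_bp() / self.length if self.length else 0.0

    def is_masked(self, positions: np.ndarray) -> np.ndarray:
        """Boolean per query position: does it fall in a masked interval?"""
        positions = np.asarray(positions)
        if self.starts.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(self.starts, positions, side="right") - 1
        inside = idx >= 0
        inside[inside] &= positions[inside] < self.ends[idx[inside]]
        return inside

    def slice(self, start: int, length: int, new_chrom: str | None = None) -> "SiteMask":
        """Mask restricted to [start, start+length), rebased to coordinate 0."""
        end = start + length
        if start < 0 or end > self.length:
            raise ValueError("slice outside mask bounds")
        keep = (self.ends > start) & (self.starts < end)
        s = np.clip(self.starts[keep], start, end) - start
        e = np.clip(self.ends[keep], start, end) - start
        return SiteMask(new_chrom or self.chrom, length, s, e)

    def to_bed(self, path, mode: str = "w") -> None:
        with open(path, mode) as fh:
            for s, e in zip(self.starts, self.ends):
                fh.write(f"{self.chrom}\t{s}\t{e}\n")


@dataclass(frozen=True)
class PopulationPair:
    """The two focal populations of a pairwise comparison."""

    pop_a: str
    pop_b: str
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if self.pop_a == self.pop_b:
            raise ValueError("population labels must be distinct")
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("each population needs >= 2 haplotypes")

    @classmethod
    def from_matrix(cls, hap: HaplotypeMatrix, pop_a: str, pop_b: str) -> "PopulationPair":
        return cls(pop_a, pop_b, hap.rows_for_pop(pop_a).size, hap.rows_for_pop(pop_b).size)


@dataclass
class DemographicModel:
    """Colonization-split history of two sympatric daughter populations.

    A founder population of diploid size ``founder_size`` colonizes the
    (crater) lake ``colonization_time`` generations ago from a source
    population of size ``source_size`` (size ``ancestral_size`` further back).
    At ``split_time`` the founder splits into two daughters that exchange
    migrants at ``migration_rate`` per generation.  Rates are per site per
    generation; sizes are diploid.
    """

    ancestral_size: int
    source_size: int
    colonization_time: int
    founder_size: int
    split_time: int
    daughter_sizes: tuple[int, int]
    migration_rate: float
    mutation_rate: float = 3.5e-9
    recombination_rate: float = 1.05e-8
    generation_time: float = 1.5

    def __post_init__(self) -> None:
        self.daughter_sizes = tuple(int(x) for x in self.daughter_sizes)
        if self.split_time > self.colonization_time:
            raise ValueError("split_time must be <= colonization_time")
        for name in ("migration_rate", "mutation_rate", "recombination_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        sizes = (self.ancestral_size, self.source_size, self.founder_size) + self.daughter_sizes
        if any(s < 2 for s in sizes):
            raise ValueError("population sizes must be >= 2 diploids")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=list)


@dataclass
class GenotypeDepthMatrix:
    """Per-sample x per-site sequencing depth; absent for simulated data."""

    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if np.any(self.depth < 0):
            raise ValueError("depths must be non-negative")


# ---------------------------------------------------------------------------
# readers / writers


def read_popfile(path) -> dict[str, str]:
    """Two-column whitespace/TSV sample->population table; '#' comments."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed popfile line: {line!r}")
            mapping[parts[0]] = parts[1]
    return mapping


def read_demographic_model(path) -> DemographicModel:
    """Demographic-model config from JSON (or YAML if the suffix says so)."""
    text = open(path).read()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    cfg["daughter_sizes"] = tuple(cfg["daughter_sizes"])
    return DemographicModel(**cfg)


def read_phased_vcf(
    path,
    popfile: Mapping[str, str] | str,
    region: str | None = None,
    require_phased: bool = True,
) -> HaplotypeMatrix:
    """Load biallelic SNPs from a phased VCF into a :class:`HaplotypeMatrix`.

    Unphased genotypes (when ``require_phased``) and half/missing calls
    become MISSING.  Positions are converted from 1-based VCF to 0-based.
    ``region`` is a samtools-style ``chrom:start-end`` string (1-based) or a
    bare chromosome name.
    """
    from cyvcf2 import VCF

    if isinstance(popfile, (str, bytes)) or hasattr(popfile, "__fspath__"):
        popfile = read_popfile(popfile)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in popfile]
    if missing:
        raise ValueError(f"sample {missing[0]!r} in VCF is absent from the popfile")

    cols: list[np.ndarray] = []
    positions: list[int] = []
    chrom = None
    it = vcf(region) if region else vcf
    for var in it:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue  # biallelic SNPs only
        if var.FORMAT is None or "GT" not in var.FORMAT:
            raise ValueError(f"missing GT field at {var.CHROM}:{var.POS}")
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError("read_phased_vcf handles one chromosome at a time; pass region=")
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a0, a1, phased = g[0], g[1], bool(g[-1])
            if a0 < 0 or a1 < 0 or (require_phased and not phased and a0 != a1):
                a0 = a1 = MISSING
            col[2 * i] = a0
            col[2 * i + 1] = a1
        cols.append(col)
        positions.append(var.POS - 1)
    vcf.close()
    if chrom is None:
        chrom = region.split(":")[0] if region else ""
    alleles = np.stack(cols, axis=1) if cols else np.empty((2 * len(samples), 0), dtype=np.int8)
    pos = np.asarray(positions, dtype=np.int64)
    order = np.argsort(pos, kind="stable")
    return HaplotypeMatrix(
        alleles[:, order],
        pos[order],
        chrom,
        samples,
        np.asarray([popfile[s] for s in samples]),
        np.zeros(len(positions), dtype=bool),
    )


def write_phased_vcf(hap: HaplotypeMatrix, path, ref: str = "A", alt: str = "T") -> None:
    """Write a minimal phased VCF (one chromosome, biallelic SNPs)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        length = int(hap.positions[-1]) + 1 if hap.n_sites else 1
        fh.write(f"##contig=<ID={hap.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(hap.sample_ids) + "\n")
        allele_str = {0: "0", 1: "1", MISSING: "."}
        for j in range(hap.n_sites):
            gts = "\t".join(
                f"{allele_str[int(hap.alleles[2 * i, j])]}|{allele_str[int(hap.alleles[2 * i + 1, j])]}"
                for i in range(hap.n_samples)
            )
            fh.write(f"{hap.chrom}\t{hap.positions[j] + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# operations


def polarize(
    hap: HaplotypeMatrix,
    outgroup: HaplotypeMatrix,
    outgroup_count: int | None = None,
    min_valid: int | None = None,
) -> HaplotypeMatrix:
    """Assign ancestral/derived states from an outgroup panel.

    A site is polarized when at least ``min_valid`` of the ``outgroup_count``
    outgroup individuals have a valid genotype and the outgroup is monomorphic
    for an allele also present in the ingroup (default: 4 of 5 individuals).
    At polarized sites the alleles are recoded so 0 = ancestral; sites failing
    the rule keep ``polarized=False`` and are excluded from unfolded
    statistics downstream.
    """
    if outgroup_count is None:
        outgroup_count = outgroup.n_samples
    if min_valid is None:
        min_valid = outgroup_count - 1
    if outgroup.n_samples != outgroup_count:
        raise ValueError("outgroup panel size does not match outgroup_count")
    if hap.chrom != outgroup.chrom or hap.n_sites != outgroup.n_sites or not np.array_equal(
        hap.positions, outgroup.positions
    ):
        raise ValueError("site coordinates of ingroup and outgroup do not match")

    og = outgroup.alleles
    valid_alleles = og != MISSING
    # a diploid is valid when both of its alleles are called
    valid_dip = valid_alleles[0::2] & valid_alleles[1::2]
    n_valid = valid_dip.sum(axis=0)

    og_masked = np.where(valid_alleles, og, MISSING)
    n_ref = ((og_masked == 0) & valid_alleles).sum(axis=0)
    n_alt = ((og_masked == 1) & valid_alleles).sum(axis=0)
    mono_ref = (n_alt == 0) & (n_ref > 0)
    mono_alt = (n_ref == 0) & (n_alt > 0)

    ing = hap.alleles
    ing_nonmiss = ing != MISSING
    has_ref = ((ing == 0) & ing_nonmiss).any(axis=0)
    has_alt = ((ing == 1) & ing_nonmiss).any(axis=0)

    ok = n_valid >= min_valid
    anc_is_ref = ok & mono_ref & has_ref
    anc_is_alt = ok & mono_alt & has_alt

    alleles = ing.copy()
    flip = np.flatnonzero(anc_is_alt)
    sub = alleles[:, flip]
    nm = sub != MISSING
    sub[nm] = 1 - sub[nm]
    alleles[:, flip] = sub
    return replace(hap, alleles=alleles, polarized=(anc_is_ref | anc_is_alt))


def apply_mask(hap: HaplotypeMatrix, mask: SiteMask) -> HaplotypeMatrix:
    """Drop sites falling in masked intervals; accessibility queries stay on
    the :class:`SiteMask` itself (``mask.accessible_bp(start, end)``)."""
    if mask.chrom != hap.chrom:
        raise ValueError(f"mask chromosome {mask.chrom!r} != data chromosome {hap.chrom!r}")
    keep = ~mask.is_masked(hap.positions)
    return hap.take_sites(np.flatnonzero(keep))


def coverage_filter(
    hap: HaplotypeMatrix,
    depth: GenotypeDepthMatrix,
    min_depth: int = 5,
    min_frac: float = 0.8,
    per_population: bool = True,
) -> HaplotypeMatrix:
    """Apply the sequencing-depth site filter.

    Genotypes with depth < ``min_depth`` are set to MISSING; a site is kept
    only if at least ``min_frac`` of individuals reach ``min_depth`` — within
    every population when ``per_population`` (the default), else panel-wide.
    """
    d = depth.depth
    if d.shape != (hap.n_samples, hap.n_sites):
        raise ValueError(
            f"depth matrix shape {d.shape} does not match samples x sites "
            f"({hap.n_samples}, {hap.n_sites})"
        )
    passing = d >= min_depth
    if per_population:
        keep = np.ones(hap.n_sites, dtype=bool)
        for pop in hap.populations():
            rows = np.flatnonzero(hap.pop_of_sample == pop)
            frac = passing[rows].mean(axis=0)
            keep &= frac >= min_frac - 1e-12
    else:
        keep = passing.mean(axis=0) >= min_frac - 1e-12

    alleles = hap.alleles.copy()
    low = np.repeat(~passing, 2, axis=0)
    alleles[low] = MISSING
    out = replace(hap, alleles=alleles)
    return out.take_sites(np.flatnonzero(keep))
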