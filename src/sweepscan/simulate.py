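"""Two-population sweep simulations under a colonization-split history.

Training loci for the window classifier are generated by a hybrid engine:

* the neutral history of the source population down to the colonization
  event is simulated with msprime (coalescent with recombination), giving
  the founding haplotypes;
* from colonization to the present the locus is propagated forward in time
  by a Wright-Fisher simulator with recombination, recurrent mutation and
  migration between the two daughter populations;
* selection enters through a selected-allele frequency trajectory drawn
  first by rejection sampling (:func:`simulate_trajectory`); linked variation
  is then propagated conditional on that trajectory, the standard conditioned
  Wright-Fisher construction.

Shared sweeps start at colonization in the pre-split lineage and continue in
both daughters; divergent sweeps start at the species split in exactly one
daughter (fair coin) while the allele drifts neutrally in the other.

Whole-genome neutral simulations for the drift-null experiment
(:func:`simulate_genome`) use msprime directly under the same demography.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import msprime
import numpy as np

from .popdata import DemographicModel, HaplotypeMatrix, SiteMask, apply_mask

__all__ = [
    "PAPER_LOCUS_BP",
    "ScaleProfile",
    "desk_profile",
    "desk_model",
    "SimParams",
    "SimInstance",
    "TrainTestSets",
    "draw_sim_params",
    "simulate_trajectory",
    "simulate_instance",
    "simulate_constant_locus",
    "mirror_mask",
    "make_training_set",
    "simulate_genome",
    "ne_swap_experiment",
    "demography_for",
    "save_training_set",
    "load_training_set",
]

PAPER_LOCUS_BP = 1_050_000

# parameter supports of the drawn simulation parameters (per 1.05-Mb locus,
# per generation)
THETA_LOCUS_RANGE = (0.000668, 0.00668)
RHO_LOCUS_MEAN = 0.018375
RHO_LOCUS_MAX = 0.055125
SEL_POS_RANGE = (0.4, 0.6)
S_RANGE = (0.01, 0.1)
F0_RANGE = (1e-5, 1e-2)

CATEGORIES = ("neutral", "shared", "divergent")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ScaleProfile:
    """How a simulation run maps the drawn per-generation rates onto a locus.

    The default profile is the full-scale 1.05-Mb locus with unscaled rates.
    The desk profile shrinks the locus to 105 kb and rescales rates and
    selection so that a small demographic model reproduces per-subwindow SNP
    densities and sweep-completion times comparable to the full-scale run
    (see docs/methods.md for the reasoning).
    """

    locus_bp: int = PAPER_LOCUS_BP
    n_subwindows: int = 21
    mutation_scale: float = 1.0
    recombination_scale: float = 1.0
    selection_scale: float = 1.0
    f_end: float = 0.8
    max_tries: int = 500

    @property
    def subwindow_bp(self) -> int:
        if self.locus_bp % self.n_subwindows:
            raise ValueError("locus_bp must divide evenly into subwindows")
        return self.locus_bp // self.n_subwindows


def desk_profile() -> ScaleProfile:
    return ScaleProfile(
        locus_bp=105_000,
        n_subwindows=21,
        mutation_scale=100.0,
        recombination_scale=100.0,
        selection_scale=15.0,
        f_end=0.8,
    )


def desk_model() -> DemographicModel:
    """Small colonization-split model paired with :func:`desk_profile`."""
    return DemographicModel(
        ancestral_size=1000,
        source_size=1000,
        colonization_time=160,
        founder_size=150,
        split_time=80,
        daughter_sizes=(300, 300),
        migration_rate=5e-4,
    )


# ---------------------------------------------------------------------------
# parameters


@dataclass
class SimParams:
    """Drawn parameters of one simulated locus."""

    theta_locus: float
    rho_locus: float
    sel_pos_rel: float
    s: float
    f0: float
    category: str
    origin: str
    onset: int
    seed: int
    locus_bp: int = PAPER_LOCUS_BP

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.origin not in ("de_novo", "standing"):
            raise ValueError(f"unknown origin {self.origin!r}")
        lo, hi = THETA_LOCUS_RANGE
        if not lo <= self.theta_locus <= hi:
            raise ValueError("theta_locus outside its support")
        if not 0 < self.rho_locus <= RHO_LOCUS_MAX:
            raise ValueError("rho_locus outside its support")
        if not SEL_POS_RANGE[0] <= self.sel_pos_rel <= SEL_POS_RANGE[1]:
            raise ValueError("sel_pos_rel outside its support")
        if self.category != "neutral":
            if not S_RANGE[0] <= self.s <= S_RANGE[1]:
                raise ValueError("selection coefficient outside its support")
            if self.origin == "standing" and not F0_RANGE[0] <= self.f0 <= F0_RANGE[1]:
                raise ValueError("standing-variation f0 outside its support")


def draw_sim_params(
    category: str,
    origin: str,
    model: DemographicModel,
    rng: np.random.Generator,
    locus_bp: int = PAPER_LOCUS_BP,
) -> SimParams:
    """Draw one parameter set from the stated distributions.

    theta ~ uniform(0.000668, 0.00668); rho ~ exponential(mean 0.018375)
    truncated by redraw at 0.055125; selected position ~ uniform(0.4, 0.6)
    of the locus; s ~ uniform(0.01, 0.1); standing-variation f0 ~
    loguniform(1e-5, 1e-2), de novo f0 = 1/(2N) of the sweeping population
    at onset.  Onset is the colonization time for shared and the split time
    for divergent selection.
    """
    theta = rng.uniform(*THETA_LOCUS_RANGE)
    rho = rng.exponential(RHO_LOCUS_MEAN)
    while rho > RHO_LOCUS_MAX or rho == 0.0:
        rho = rng.exponential(RHO_LOCUS_MEAN)
    pos = rng.uniform(*SEL_POS_RANGE)
    if category == "neutral":
        s, f0, onset = 0.0, 0.0, 0
    else:
        s = rng.uniform(*S_RANGE)
        onset = model.colonization_time if category == "shared" else model.split_time
        if origin == "standing":
            f0 = float(np.exp(rng.uniform(np.log(F0_RANGE[0]), np.log(F0_RANGE[1]))))
        else:
            n_onset = model.founder_size if category == "shared" else model.daughter_sizes[0]
            f0 = 1.0 / (2 * n_onset)
    seed = int(rng.integers(1, 2**31 - 1))
    return SimParams(theta, rho, pos, s, f0, category, origin, onset, seed, locus_bp)


@dataclass
class SimInstance:
    """One simulated locus with its true class label and provenance."""

    params: SimParams
    hap: HaplotypeMatrix
    label: str
    mask: SiteMask | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class TrainTestSets:
    train: list[SimInstance]
    test: list[SimInstance]


# ---------------------------------------------------------------------------
# selected-allele trajectories


def simulate_trajectory(
    s: float,
    f0: float,
    N_path,
    onset: int,
    rng: np.random.Generator,
    f_end: float | None = 0.8,
    max_tries: int = 500,
) -> np.ndarray:
    """Forward Wright-Fisher frequency path of an additively selected allele.

    Genotype fitnesses are 1, 1+s/2, 1+s; each generation the deterministic
    update p' = p(1 + (s/2)(1+p)) / (1 + s p) is followed by binomial
    sampling of 2N gametes.  ``N_path`` is a scalar diploid size or an array
    of length ``onset`` (forward order).  When ``f_end`` is not None the path
    is rejection-sampled until the final frequency is >= f_end.

    Returns an array of length ``onset + 1``: index 0 holds f0 at onset,
    index ``onset`` the frequency at sampling time.
    """
    if not 0 < f0 <= 1:
        raise ValueError("f0 must be in (0, 1]")
    if s < 0:
        raise ValueError("s must be >= 0")
    N = np.broadcast_to(np.asarray(N_path, dtype=np.int64), (onset,))
    if f0 >= 1.0:
        return np.ones(onset + 1)
    for _ in range(max_tries):
        path = np.empty(onset + 1)
        path[0] = x = f0
        lost = False
        for t in range(onset):
            if x >= 1.0:
                path[t + 1 :] = 1.0
                break
            xp = x * (1 + 0.5 * s * (1 + x)) / (1 + s * x)
            two_n = 2 * int(N[t])
            x = rng.binomial(two_n, min(xp, 1.0)) / two_n
            path[t + 1] = x
            if x == 0.0:
                path[t + 1 :] = 0.0
                lost = True
                break
        if lost:
            if f_end is None:
                return path
            continue
        if f_end is None or path[onset] >= f_end:
            return path
    raise RuntimeError(
        "selected-allele trajectory failed the conditioning after "
        f"{max_tries} tries; consider a larger s or f0"
    )


def _draw_trajectories(
    params: SimParams,
    model: DemographicModel,
    s_eng: float,
    rng: np.random.Generator,
    profile: ScaleProfile,
) -> dict:
    """Category-specific trajectories: 'anc' anchored at colonization,
    'a'/'b' anchored at the split.  Divergent sweeps pick the swept daughter
    by fair coin (recorded under 'swept')."""
    col, spl = model.colonization_time, model.split_time
    if params.category == "neutral":
        return {"anc": None, "a": None, "b": None, "swept": None}
    if params.category == "divergent":
        swept = "a" if rng.random() < 0.5 else "b"
        nd = model.daughter_sizes[0 if swept == "a" else 1]
        # quantize f0 to the discrete allele-copy grid (at least one copy)
        f0 = max(1, round(params.f0 * 2 * nd)) / (2 * nd)
        traj = simulate_trajectory(
            s_eng, f0, nd, spl, rng, profile.f_end, profile.max_tries
        )
        out = {"anc": None, "a": None, "b": None, "swept": swept}
        out[swept] = traj
        return out
    # shared: sweep in the pre-split lineage, continuing in both daughters
    n_f = 2 * model.founder_size
    f0 = max(1, round(params.f0 * n_f)) / n_f
    for _ in range(profile.max_tries):
        anc = simulate_trajectory(
            s_eng, f0, model.founder_size, col - spl, rng, f_end=None, max_tries=1
        )
        x_split = anc[-1]
        if x_split <= 0.0:
            continue
        try:
            ta = simulate_trajectory(
                s_eng, x_split, model.daughter_sizes[0], spl, rng, profile.f_end, 20
            )
            tb = simulate_trajectory(
                s_eng, x_split, model.daughter_sizes[1], spl, rng, profile.f_end, 20
            )
        except RuntimeError:
            continue
        return {"anc": anc, "a": ta, "b": tb, "swept": "both"}
    raise RuntimeError(
        "shared-sweep trajectory failed the conditioning after "
        f"{profile.max_tries} tries; consider a larger s or f0"
    )


# ---------------------------------------------------------------------------
# forward Wright-Fisher locus engine


class _LocusState:
    """Haplotypes of 1-2 populations over a shared, growing set of sites."""

    def __init__(self, locus_bp: float, positions: np.ndarray, pops: list[np.ndarray]):
        self.L = float(locus_bp)
        s0 = positions.size
        cap = max(2 * s0 + 256, 1024)
        self.pos = np.empty(cap)
        self.pos[:s0] = positions
        self.S = s0
        self.pops = []
        for H in pops:
            M = np.zeros((H.shape[0], cap), dtype=np.int8)
            M[:, :s0] = H
            self.pops.append(M)
        self.sel_col = -1

    def _grow(self, extra: int) -> None:
        if self.S + extra <= self.pos.size:
            return
        cap = max(2 * self.pos.size, self.S + extra + 256)
        pos = np.empty(cap)
        pos[: self.S] = self.pos[: self.S]
        self.pos = pos
        for i, H in enumerate(self.pops):
            M = np.zeros((H.shape[0], cap), dtype=np.int8)
            M[:, : self.S] = H[:, : self.S]
            self.pops[i] = M

    def add_mutations(self, pop_idx: int, n_new: int, rng: np.random.Generator) -> None:
        if n_new == 0:
            return
        self._grow(n_new)
        H = self.pops[pop_idx]
        rows = rng.integers(0, H.shape[0], n_new)
        cols = np.arange(self.S, self.S + n_new)
        self.pos[cols] = rng.random(n_new) * self.L
        H[rows, cols] = 1
        self.S += n_new

    def add_selected(self, pop_idx: int, rel_pos: float, n_carriers: int, rng) -> None:
        self._grow(1)
        H = self.pops[pop_idx]
        carriers = rng.choice(H.shape[0], size=n_carriers, replace=False)
        self.pos[self.S] = rel_pos * self.L
        H[carriers, self.S] = 1
        self.sel_col = self.S
        self.S += 1

    def compact(self) -> None:
        tot = sum(H[:, : self.S].sum(axis=0, dtype=np.int64) for H in self.pops)
        n_tot = sum(H.shape[0] for H in self.pops)
        keep = (tot > 0) & (tot < n_tot)
        if self.sel_col >= 0:
            keep[self.sel_col] = True
        idx = np.flatnonzero(keep)
        if idx.size == self.S:
            return
        self.pos[: idx.size] = self.pos[idx]
        for H in self.pops:
            H[:, : idx.size] = H[:, idx]
            H[:, idx.size : self.S] = 0
        if self.sel_col >= 0:
            self.sel_col = int(np.searchsorted(idx, self.sel_col))
        self.S = idx.size


def _offspring(
    state: _LocusState,
    pop_idx: int,
    n_off: int,
    m: float,
    r_locus: float,
    rng: np.random.Generator,
    k_ben: int | None = None,
) -> np.ndarray:
    """One conditioned Wright-Fisher generation for one population.

    Each offspring gamete recombines the two strands of a parent diploid
    (Poisson(r_locus) crossovers at uniform positions).  When ``k_ben`` is
    given, exactly that many gametes are drawn from beneficial-carrying focal
    strands and forced to transmit the focal allele at the selected site (the
    crossover mosaic is relabelled, which preserves its distribution);
    likewise the remaining gametes transmit the non-beneficial allele.
    Migrant gametes (probability ``m``) come from the other population and
    are never forced.
    """
    S = state.S
    pos = state.pos[:S]
    own = state.pops[pop_idx]
    two_pops = len(state.pops) == 2
    other = state.pops[1 - pop_idx] if two_pops else None

    focal = np.zeros(n_off, dtype=np.int64)
    from_other = np.zeros(n_off, dtype=bool)
    forced = np.zeros(n_off, dtype=bool)

    if k_ben is None:
        if two_pops and m > 0:
            from_other = rng.random(n_off) < m
        res = np.flatnonzero(~from_other)
        focal[res] = rng.integers(0, own.shape[0], res.size)
        mig = np.flatnonzero(from_other)
        if mig.size:
            focal[mig] = rng.integers(0, other.shape[0], mig.size)
    else:
        sel = state.sel_col
        ben = np.flatnonzero(own[:, sel] == 1)
        non = np.flatnonzero(own[:, sel] == 0)
        k = min(max(k_ben, 0), n_off)
        if k > 0 and ben.size == 0:
            raise RuntimeError("trajectory requires beneficial alleles but none remain")
        if k < n_off and non.size == 0:
            k = n_off
        if k:
            focal[:k] = ben[rng.integers(0, ben.size, k)]
            forced[:k] = True
        if k < n_off:
            tail = np.arange(k, n_off)
            if two_pops and m > 0:
                from_other[tail] = rng.random(tail.size) < m
            res = tail[~from_other[tail]]
            focal[res] = non[rng.integers(0, non.size, res.size)]
            forced[res] = True
            mig = tail[from_other[tail]]
            if mig.size:
                focal[mig] = rng.integers(0, other.shape[0], mig.size)

    partner = focal ^ 1
    if not from_other.any():
        out = own[focal, :S]
    else:
        out = np.empty((n_off, S), dtype=np.int8)
        res = ~from_other
        out[res] = own[focal[res], :S]
        out[from_other] = other[focal[from_other], :S]

    n_x = rng.poisson(r_locus, n_off)
    sel = state.sel_col
    one = np.flatnonzero(n_x == 1)
    if one.size:
        # single crossover (the common case), fully vectorized
        xs = rng.random(one.size) * state.L
        par = pos[None, :] > xs[:, None]
        if sel >= 0:
            flip = forced[one] & par[:, sel]
            par[flip] = ~par[flip]
        prows = np.empty((one.size, S), dtype=np.int8)
        o_res = ~from_other[one]
        prows[o_res] = own[partner[one[o_res]], :S]
        if not o_res.all():
            prows[~o_res] = other[partner[one[~o_res]], :S]
        rows = out[one]
        # xor-select: rows where par is False, prows where True (int-exact)
        out[one] = rows ^ ((rows ^ prows) & par)
    for i in np.flatnonzero(n_x >= 2):
        xp = rng.random(n_x[i]) * state.L
        par = np.zeros(S, dtype=bool)
        for x in xp:
            par ^= pos > x
        if forced[i] and sel >= 0 and par[sel]:
            par = ~par
        src = other if from_other[i] else own
        prow = src[partner[i], :S]
        out[i, par] = prow[par]

    if k_ben is not None:
        out = out[rng.permutation(n_off)]  # decouple gamete pairing from the allele
    return out


def _msprime_founders(
    model: DemographicModel, n_hap: int, locus_bp: int, u_site: float, r_site: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Neutral founding haplotypes: a sample from the source population at
    the moment of colonization (source size back one colonization-length
    epoch, ancestral size beyond)."""
    dem = msprime.Demography()
    dem.add_population(name="SRC", initial_size=model.source_size)
    dem.add_population_parameters_change(
        time=model.colonization_time, initial_size=model.ancestral_size, population="SRC"
    )
    ts = msprime.sim_ancestry(
        samples={"SRC": n_hap // 2},
        demography=dem,
        sequence_length=locus_bp,
        recombination_rate=r_site,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=u_site,
        random_seed=seed + 1,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
    )
    H = mts.genotype_matrix().T.astype(np.int8)
    pos = mts.tables.sites.position.copy()
    return H, pos


def _state_to_matrix(
    state: _LocusState,
    sample_rows: list[np.ndarray],
    pair_labels: tuple[str, str],
    chrom: str,
    rng: np.random.Generator,
) -> HaplotypeMatrix:
    """Sampled panel -> HaplotypeMatrix: integer positions, sorted columns,
    only sites segregating in the combined sample."""
    panel = np.concatenate(
        [state.pops[i][rows][:, : state.S] for i, rows in enumerate(sample_rows)], axis=0
    )
    tot = panel.sum(axis=0, dtype=np.int64)
    seg = np.flatnonzero((tot > 0) & (tot < panel.shape[0]))
    panel = panel[:, seg]
    pos = np.floor(state.pos[seg]).astype(np.int64)
    order = np.argsort(pos, kind="stable")
    pos, panel = pos[order], panel[:, order]
    uniq = np.concatenate([[True], np.diff(pos) > 0]) if pos.size else np.ones(0, bool)
    pos, panel = pos[uniq], panel[:, uniq]
    n_a = sample_rows[0].size
    n_b = sample_rows[1].size if len(sample_rows) > 1 else 0
    sample_ids = [f"{pair_labels[0]}_{i}" for i in range(n_a // 2)] + [
        f"{pair_labels[1]}_{i}" for i in range(n_b // 2)
    ]
    pops = np.array([pair_labels[0]] * (n_a // 2) + [pair_labels[1]] * (n_b // 2))
    return HaplotypeMatrix(
        panel, pos, chrom, sample_ids, pops, np.ones(pos.size, dtype=bool)
    )


def simulate_instance(
    params: SimParams,
    model: DemographicModel,
    n_a: int,
    n_b: int,
    rng: np.random.Generator | None = None,
    profile: ScaleProfile = ScaleProfile(),
    pair_labels: tuple[str, str] = ("A", "B"),
    chrom: str = "locus",
) -> SimInstance:
    """Simulate one labelled two-population locus.

    ``n_a``/``n_b`` are sampled haplotype counts (even; two per diploid).
    The output matrix is polarized by construction (1 = derived).
    """
    if n_a % 2 or n_b % 2:
        raise ValueError("sample sizes must be even (diploid sampling)")
    if model.split_time < 1:
        raise ValueError("split_time must be >= 1 generation")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    L = profile.locus_bp
    scale = L / PAPER_LOCUS_BP
    u_locus = params.theta_locus * scale * profile.mutation_scale
    r_locus = params.rho_locus * scale * profile.recombination_scale
    s_eng = params.s * profile.selection_scale

    traj = _draw_trajectories(params, model, s_eng, rng, profile)

    n_f = 2 * model.founder_size
    seed = int(rng.integers(1, 2**31 - 1))
    H0, pos0 = _msprime_founders(model, n_f, L, u_locus / L, r_locus / L, seed)
    state = _LocusState(L, pos0, [H0])

    col, spl = model.colonization_time, model.split_time
    if params.category == "shared":
        k0 = max(1, round(params.f0 * n_f))
        state.add_selected(0, params.sel_pos_rel, k0, rng)
    m = model.migration_rate
    n_da, n_db = (2 * x for x in model.daughter_sizes)

    for g in range(col - 1, -1, -1):  # g = generations ago of the offspring
        if g >= spl:  # founder phase
            k = None
            if traj["anc"] is not None:
                k = round(traj["anc"][col - g] * n_f)
            new = _offspring(state, 0, n_f, 0.0, r_locus, rng, k)
            state.pops[0][:, : state.S] = new
        elif g == spl - 1:  # the split: both daughters drawn from the founder
            if params.category == "divergent":
                k0 = max(1, round(params.f0 * n_f))
                state.add_selected(0, params.sel_pos_rel, k0, rng)
            offs = []
            for d, n_d in (("a", n_da), ("b", n_db)):
                k = None
                if traj[d] is not None:
                    k = round(traj[d][spl - g] * n_d)
                offs.append(_offspring(state, 0, n_d, 0.0, r_locus, rng, k))
            cap = state.pos.size
            state.pops = [np.zeros((n_da, cap), np.int8), np.zeros((n_db, cap), np.int8)]
            state.pops[0][:, : state.S] = offs[0]
            state.pops[1][:, : state.S] = offs[1]
        else:  # two daughters with migration
            offs = []
            for i, (d, n_d) in enumerate((("a", n_da), ("b", n_db))):
                k = None
                if traj[d] is not None:
                    k = round(traj[d][spl - g] * n_d)
                offs.append(_offspring(state, i, n_d, m, r_locus, rng, k))
            for i in range(2):
                state.pops[i][:, : state.S] = offs[i]
        for i, H in enumerate(state.pops):
            n_new = rng.poisson(u_locus * H.shape[0])
            state.add_mutations(i, n_new, rng)
        if g % 16 == 0:
            state.compact()

    state.compact()
    rows_a = np.sort(
        np.repeat(2 * rng.choice(n_da // 2, n_a // 2, replace=False), 2)
        + np.tile([0, 1], n_a // 2)
    )
    rows_b = np.sort(
        np.repeat(2 * rng.choice(n_db // 2, n_b // 2, replace=False), 2)
        + np.tile([0, 1], n_b // 2)
    )
    hap = _state_to_matrix(state, [rows_a, rows_b], pair_labels, chrom, rng)
    meta = {
        "swept": traj["swept"],
        "sel_pos_bp": int(params.sel_pos_rel * L),
        "final_freq_a": float(state.pops[0][:, state.sel_col].mean()) if state.sel_col >= 0 else None,
        "final_freq_b": float(state.pops[1][:, state.sel_col].mean()) if state.sel_col >= 0 else None,
    }
    return SimInstance(params, hap, params.category, None, meta)


def mirror_mask(
    inst: SimInstance, empirical_mask: SiteMask, rng: np.random.Generator
) -> SimInstance:
    """Apply a uniformly random locus-length slice of an empirical mask to a
    simulated locus, mirroring its missing-data pattern."""
    L = int(inst.params.locus_bp)
    if empirical_mask.length < L:
        raise ValueError("empirical mask shorter than the simulated locus")
    start = int(rng.integers(0, empirical_mask.length - L + 1))
    sl = empirical_mask.slice(start, L, new_chrom=inst.hap.chrom)
    hap = apply_mask(inst.hap, sl)
    meta = dict(inst.meta, mask_slice_start=start)
    return SimInstance(inst.params, hap, inst.label, sl, meta)


def make_training_set(
    model: DemographicModel,
    pair_sizes: tuple[int, int],
    n_train_per_class: int = 4000,
    n_test_per_class: int = 2000,
    mask: SiteMask | None = None,
    rng: np.random.Generator | None = None,
    profile: ScaleProfile = ScaleProfile(),
    categories: tuple[str, ...] = CATEGORIES,
    standing_fraction: float = 0.5,
    s: float | None = None,
) -> TrainTestSets:
    """Balanced labelled train/test collections of simulated loci.

    Selected categories mix de novo and standing origins at
    ``standing_fraction``.  ``s`` pins the selection coefficient instead of
    drawing it (the strong-signal regime fixes s = 0.1).  Each instance
    records its own seed, so the whole set is reproducible from the master
    rng."""
    if rng is None:
        rng = np.random.default_rng()
    n_a, n_b = pair_sizes
    out = {"train": [], "test": []}
    for split_name, n_per in (("train", n_train_per_class), ("test", n_test_per_class)):
        for cat in categories:
            for _ in range(n_per):
                origin = (
                    "standing" if cat != "neutral" and rng.random() < standing_fraction else "de_novo"
                )
                params = draw_sim_params(cat, origin, model, rng, profile.locus_bp)
                if s is not None and cat != "neutral":
                    params = replace(params, s=s)
                inst = simulate_instance(
                    params, model, n_a, n_b,
                    np.random.default_rng(params.seed), profile,
                )
                if mask is not None:
                    inst = mirror_mask(inst, mask, np.random.default_rng(params.seed + 1))
                out[split_name].append(inst)
    return TrainTestSets(out["train"], out["test"])


def simulate_constant_locus(
    N: int,
    n_sample: int,
    u_locus: float,
    r_locus: float,
    t_forward: int,
    locus_bp: int,
    rng: np.random.Generator,
    chrom: str = "locus",
) -> HaplotypeMatrix:
    """Neutral constant-size single-population locus for engine calibration.

    The whole population (2N haplotypes) is initialized at coalescent
    equilibrium with msprime and then propagated ``t_forward`` generations by
    the forward Wright-Fisher machinery, after which ``n_sample`` haplotypes
    are drawn.  At equilibrium the sampled Watterson estimator should be
    unbiased for theta = 4*N*u_locus and Tajima's D centred on zero.
    """
    if n_sample % 2:
        raise ValueError("n_sample must be even (diploid sampling)")
    dem = msprime.Demography()
    dem.add_population(name="P", initial_size=N)
    seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples={"P": N},
        demography=dem,
        sequence_length=locus_bp,
        recombination_rate=r_locus / locus_bp,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=u_locus / locus_bp, random_seed=seed + 1,
        model=msprime.BinaryMutationModel(), discrete_genome=False,
    )
    H0 = mts.genotype_matrix().T.astype(np.int8)
    pos0 = mts.tables.sites.position.copy()
    state = _LocusState(locus_bp, pos0, [H0])
    n_hap = 2 * N
    for g in range(t_forward):
        new = _offspring(state, 0, n_hap, 0.0, r_locus, rng, None)
        state.pops[0][:, : state.S] = new
        state.add_mutations(0, int(rng.poisson(u_locus * n_hap)), rng)
        if g % 16 == 0:
            state.compact()
    state.compact()
    rows = np.sort(
        np.repeat(2 * rng.choice(N, n_sample // 2, replace=False), 2)
        + np.tile([0, 1], n_sample // 2)
    )
    panel = state.pops[0][rows][:, : state.S]
    tot = panel.sum(axis=0, dtype=np.int64)
    seg = np.flatnonzero((tot > 0) & (tot < panel.shape[0]))
    panel = panel[:, seg]
    pos = np.floor(state.pos[seg]).astype(np.int64)
    order = np.argsort(pos, kind="stable")
    pos, panel = pos[order], panel[:, order]
    uniq = np.concatenate([[True], np.diff(pos) > 0]) if pos.size else np.ones(0, bool)
    pos, panel = pos[uniq], panel[:, uniq]
    ids = [f"P_{i}" for i in range(n_sample // 2)]
    return HaplotypeMatrix(
        panel, pos, chrom, ids, np.array(["P"] * (n_sample // 2)),
        np.ones(pos.size, dtype=bool),
    )


# ---------------------------------------------------------------------------
# whole-genome neutral simulation and the Ne-swap experiment


def demography_for(
    model: DemographicModel,
    pair_labels: tuple[str, str] = ("A", "B"),
    outgroup_split_time: int | None = None,
    outgroup_size: int | None = None,
) -> msprime.Demography:
    """The msprime demography of the colonization-split model; optionally an
    outgroup lineage diverging from the source deep in the past."""
    a, b = pair_labels
    dem = msprime.Demography()
    dem.add_population(name=a, initial_size=model.daughter_sizes[0])
    dem.add_population(name=b, initial_size=model.daughter_sizes[1])
    dem.add_population(name="FND", initial_size=model.founder_size)
    dem.add_population(name="SRC", initial_size=model.source_size)
    dem.set_symmetric_migration_rate([a, b], model.migration_rate)
    dem.add_population_split(time=model.split_time, derived=[a, b], ancestral="FND")
    dem.add_population_split(time=model.colonization_time, derived=["FND"], ancestral="SRC")
    dem.add_population_parameters_change(
        time=2 * model.colonization_time, initial_size=model.ancestral_size, population="SRC"
    )
    if outgroup_split_time is not None:
        dem.add_population(name="OUT", initial_size=outgroup_size or model.ancestral_size)
        dem.add_population(name="ROOT", initial_size=model.ancestral_size)
        dem.add_population_split(
            time=outgroup_split_time, derived=["SRC", "OUT"], ancestral="ROOT"
        )
    dem.sort_events()
    return dem


def _matrix_from_ts(
    mts, chrom: str, sample_pops: list[tuple[str, int]]
) -> HaplotypeMatrix:
    H = mts.genotype_matrix().T.astype(np.int8)
    pos = np.floor(mts.tables.sites.position).astype(np.int64)
    order = np.argsort(pos, kind="stable")
    pos, H = pos[order], H[:, order]
    uniq = np.concatenate([[True], np.diff(pos) > 0]) if pos.size else np.ones(0, bool)
    pos, H = pos[uniq], H[:, uniq]
    tot = H.sum(axis=0, dtype=np.int64)
    seg = (tot > 0) & (tot < H.shape[0])
    pos, H = pos[seg], H[:, seg]
    sample_ids, pops = [], []
    for label, n_dip in sample_pops:
        sample_ids += [f"{label}_{i}" for i in range(n_dip)]
        pops += [label] * n_dip
    return HaplotypeMatrix(H, pos, chrom, sample_ids, np.array(pops), np.ones(pos.size, bool))


def simulate_genome(
    model: DemographicModel,
    chrom_lengths: dict[str, int],
    n_replicates: int,
    n_a: int,
    n_b: int,
    rng: np.random.Generator,
    mutation_scale: float = 1.0,
    recombination_scale: float = 1.0,
    pair_labels: tuple[str, str] = ("A", "B"),
) -> list[dict[str, HaplotypeMatrix]]:
    """Neutral whole-genome replicates under the model: per replicate, one
    phased two-population matrix per chromosome."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    dem = demography_for(model, pair_labels)
    u = model.mutation_rate * mutation_scale
    r = model.recombination_rate * recombination_scale
    out = []
    for _ in range(n_replicates):
        rep = {}
        for chrom, length in chrom_lengths.items():
            seed = int(rng.integers(1, 2**31 - 1))
            ts = msprime.sim_ancestry(
                samples={pair_labels[0]: n_a // 2, pair_labels[1]: n_b // 2},
                demography=dem,
                sequence_length=length,
                recombination_rate=r,
                random_seed=seed,
            )
            mts = msprime.sim_mutations(
                ts, rate=u, random_seed=seed + 1,
                model=msprime.BinaryMutationModel(), discrete_genome=False,
            )
            rep[chrom] = _matrix_from_ts(
                mts, chrom, [(pair_labels[0], n_a // 2), (pair_labels[1], n_b // 2)]
            )
        out.append(rep)
    return out


def ne_swap_experiment(
    model_a: DemographicModel, model_b: DemographicModel
) -> tuple[DemographicModel, DemographicModel]:
    """Exchange past and present effective sizes between two models; times,
    migration and rates stay put.  Applying it twice restores the originals."""
    size_fields = ("ancestral_size", "source_size", "founder_size", "daughter_sizes")
    kw_a = {f: getattr(model_b, f) for f in size_fields}
    kw_b = {f: getattr(model_a, f) for f in size_fields}
    return replace(model_a, **kw_a), replace(model_b, **kw_b)


# ---------------------------------------------------------------------------
# serialization: plain-text instances + JSON manifest


def _save_instance(inst: SimInstance, directory: str, name: str) -> None:
    hap = inst.hap
    with open(os.path.join(directory, name + ".hap.txt"), "w") as fh:
        fh.write(f"#chrom={hap.chrom}\n")
        fh.write("#positions=" + ",".join(map(str, hap.positions.tolist())) + "\n")
        fh.write("#samples=" + ",".join(hap.sample_ids) + "\n")
        fh.write("#pops=" + ",".join(map(str, hap.pop_of_sample.tolist())) + "\n")
        for row in hap.alleles:
            fh.write("".join("." if a < 0 else str(int(a)) for a in row) + "\n")
    side = {
        "params": inst.params.__dict__,
        "label": inst.label,
        "meta": {k: v for k, v in inst.meta.items()},
        "mask": None
        if inst.mask is None
        else {
            "length": int(inst.mask.length),
            "starts": inst.mask.starts.tolist(),
            "ends": inst.mask.ends.tolist(),
        },
    }
    with open(os.path.join(directory, name + ".json"), "w") as fh:
        json.dump(side, fh, indent=0, sort_keys=True)


def _load_instance(directory: str, name: str) -> SimInstance:
    with open(os.path.join(directory, name + ".json")) as fh:
        side = json.load(fh)
    rows = []
    header: dict[str, str] = {}
    with open(os.path.join(directory, name + ".hap.txt")) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                k, v = line[1:].split("=", 1)
                header[k] = v
            else:
                rows.append([-1 if c == "." else int(c) for c in line])
    pos = (
        np.array([int(x) for x in header["positions"].split(",") if x], dtype=np.int64)
        if header["positions"]
        else np.empty(0, np.int64)
    )
    alleles = np.array(rows, dtype=np.int8) if rows else np.empty((0, 0), np.int8)
    hap = HaplotypeMatrix(
        alleles,
        pos,
        header["chrom"],
        header["samples"].split(","),
        np.array(header["pops"].split(",")),
        np.ones(pos.size, dtype=bool),
    )
    params = SimParams(**side["params"])
    mask = None
    if side["mask"] is not None:
        mask = SiteMask(
            hap.chrom,
            side["mask"]["length"],
            np.array(side["mask"]["starts"], np.int64),
            np.array(side["mask"]["ends"], np.int64),
        )
    return SimInstance(params, hap, side["label"], mask, side["meta"])


def save_training_set(sets: TrainTestSets, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    manifest = {"train": [], "test": []}
    for split_name, insts in (("train", sets.train), ("test", sets.test)):
        for i, inst in enumerate(insts):
            name = f"{split_name}_{i:05d}"
            _save_instance(inst, directory, name)
            manifest[split_name].append({"name": name, "label": inst.label, "seed": inst.params.seed})
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def load_training_set(directory: str) -> TrainTestSets:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    return TrainTestSets(
        [_load_instance(directory, rec["name"]) for rec in manifest["train"]],
        [_load_instance(directory, rec["name"]) for rec in manifest["test"]],
    )
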