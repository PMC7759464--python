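import tempfile
from types import SimpleNamespace

import numpy as np
import pytest

from sweepscan.popdata import HaplotypeMatrix, PopulationPair


def random_matrix(
    rng: np.random.Generator,
    n_hap: int,
    n_sites: int,
    chrom: str = "chr1",
    span: int = 10_000,
    missing_frac: float = 0.0,
    pops: tuple[str, ...] | None = None,
) -> HaplotypeMatrix:
    """A random polymorphic haplotype matrix for statistic tests."""
    while True:
        alleles = (rng.random((n_hap, n_sites)) < rng.uniform(0.1, 0.9, n_sites)).astype(
            np.int8
        )
        tot = alleles.sum(axis=0)
        if n_sites == 0 or np.all((tot > 0) & (tot < n_hap)):
            break
    if missing_frac > 0:
        miss = rng.random(alleles.shape) < missing_frac
        alleles[miss] = -1
    positions = np.sort(rng.choice(span, size=n_sites, replace=False)).astype(np.int64)
    n_samples = n_hap // 2
    if pops is None:
        pops = ("A",) * n_samples
    sample_ids = [f"s{i}" for i in range(n_samples)]
    return HaplotypeMatrix(
        alleles, positions, chrom, sample_ids, np.asarray(pops), np.ones(n_sites, bool)
    )


def random_two_pop_matrix(rng, n_a_dip, n_b_dip, n_sites, **kw):
    pops = ("A",) * n_a_dip + ("B",) * n_b_dip
    hap = random_matrix(rng, 2 * (n_a_dip + n_b_dip), n_sites, pops=pops, **kw)
    return hap, PopulationPair("A", "B", 2 * n_a_dip, 2 * n_b_dip)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


# ---------------------------------------------------------------------------
# session-scoped desk-profile pipeline shared by the acceptance tests


DESK_PLANTED = [
    ("chr1", 200_000, "divergent", 0.1, "de_novo"),
    ("chr1", 600_000, "divergent", 0.1, "de_novo"),
    ("chr1", 1_500_000, "divergent", 0.1, "de_novo"),
    ("chr2", 300_000, "divergent", 0.1, "de_novo"),
    ("chr2", 1_200_000, "divergent", 0.1, "de_novo"),
]


@pytest.fixture(scope="session")
def desk_cohorts():
    """A synthetic genome with five planted strong divergent sweeps and a
    fully neutral genome, both 38%-masked."""
    from sweepscan import simulate as sim
    from sweepscan import synthfix as sf

    model, prof = sim.desk_model(), sim.desk_profile()
    with tempfile.TemporaryDirectory() as d:
        planted = sf.make_cohort(
            sf.FixtureSpec(
                n_chroms=2, chrom_bp=2_000_000, model=model, profile=prof,
                planted=DESK_PLANTED, masked_fraction=0.38, seed=101,
            ),
            d,
        )
    with tempfile.TemporaryDirectory() as d:
        neutral = sf.make_cohort(
            sf.FixtureSpec(
                n_chroms=2, chrom_bp=2_000_000, model=model, profile=prof,
                planted=[], masked_fraction=0.38, seed=202,
            ),
            d,
        )
    return SimpleNamespace(planted=planted, neutral=neutral, model=model, profile=prof)


@pytest.fixture(scope="session")
def desk_training(desk_cohorts):
    """The desk-profile classifier experiment: 400/200 loci per class in the
    strong-selection regime (s = 0.1), one ensemble trained on the plain
    features and one on mask-mirrored features for the genome scan."""
    from sweepscan import simulate as sim
    from sweepscan.classifier import instances_to_features, train_classifier

    model, prof = desk_cohorts.model, desk_cohorts.profile
    sets = sim.make_training_set(
        model, (40, 40), 400, 200, None, np.random.default_rng(123), prof, s=0.1
    )
    x_train, y_train, _ = instances_to_features(sets.train)
    x_test, y_test, _ = instances_to_features(sets.test)

    mask = desk_cohorts.planted.masks["chr1"]
    masked_train = [
        sim.mirror_mask(i, mask, np.random.default_rng(i.params.seed + 1))
        for i in sets.train
    ]
    masked_test = [
        sim.mirror_mask(i, mask, np.random.default_rng(i.params.seed + 1))
        for i in sets.test
    ]
    xm_train, ym_train, _ = instances_to_features(masked_train)
    xm_test, ym_test, _ = instances_to_features(masked_test)

    clf, report = train_classifier(
        (x_train, y_train), (x_test, y_test), rng=np.random.default_rng(7)
    )
    # the scan asserts divergent selection at 0.99 posterior support, so its
    # classifier gets a larger ensemble for better-calibrated posteriors
    clf_masked, report_masked = train_classifier(
        (xm_train, ym_train), (xm_test, ym_test), rng=np.random.default_rng(7),
        n_members=5,
    )
    return SimpleNamespace(
        x_train=x_train, y_train=y_train, x_test=x_test, y_test=y_test,
        clf=clf, report=report, clf_masked=clf_masked, report_masked=report_masked,
    )
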