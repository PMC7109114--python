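import pytest

from bsascan.synthetic_data import DEFAULT_ROLES, CrossConfig, simulate_dataset
from bsascan.variant_io import AlleleDepth, VariantRecord


@pytest.fixture(scope="session")
def roles():
    return DEFAULT_ROLES


@pytest.fixture(scope="session")
def small_config():
    """A fast miniature cross: three unlinked background chromosomes plus
    the causal chromosome.  Scans of this fixture should use windows
    proportionate to the 2-4 Mb chromosomes (e.g. 500 kb)."""
    return CrossConfig(
        chrom_lengths={"Chr01": 2_000_000, "Chr02": 2_000_000,
                       "Chr03": 2_000_000, "Chr04": 4_000_000},
        causal_chrom="Chr04",
        causal_pos=2_000_000,
        marker_spacing=20_000,
        n_pattern_decoys=6,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


def make_variant(chrom, pos, ref, alts, depths_by_role):
    """Build a VariantRecord from {role: tuple-or-None} depth shorthand."""
    depths = {
        role: AlleleDepth.missing() if counts is None else AlleleDepth(tuple(counts))
        for role, counts in depths_by_role.items()
    }
    return VariantRecord(chrom, pos, ref, tuple(alts), depths)


# the depth pattern of the causal-candidate row of the study's variant table:
# mutant parent het (10,5), original hom (14,0), other parent hom (20,0),
# green pool hom (39,0), red pool het (24,9)
TABLE_ROW_DEPTHS = {
    "red_parent": (10, 5),
    "original": (14, 0),
    "green_parent": (20, 0),
    "green_pool": (39, 0),
    "red_pool": (24, 9),
}


@pytest.fixture()
def table_row_variant():
    return make_variant("Chr04", 18_388_296, "AGCAGCTGAAGTTCC", ["A"], TABLE_ROW_DEPTHS)
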