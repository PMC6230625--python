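import numpy as np
import pytest

from strandmeth import Amplicon, MethylationProfile, synthetic_reference
from strandmeth.calling import CloneProfile


@pytest.fixture(scope="session")
def tsdr_amplicon() -> Amplicon:
    """Synthetic 15-CpG top-strand amplicon (TSDR-sized)."""
    return Amplicon.from_genomic("FOXP3_TSDR", synthetic_reference("FOXP3_TSDR", 15))


@pytest.fixture(scope="session")
def small_amplicon() -> Amplicon:
    """Tiny 3-CpG amplicon for hand-checkable cases."""
    return Amplicon("mini", "AACGTTCCAACGTTACCGTA")


def make_profiles(
    calls_rows: np.ndarray,
    group=("D1", "Tcon", "mini", "top"),
    efficiency: float = 1.0,
) -> list[CloneProfile]:
    """Build QC-passing CloneProfiles from a calls matrix."""
    return [
        CloneProfile(
            clone_id=f"c{i:03d}",
            group=group,
            calls=np.asarray(row, dtype=float),
            conversion_efficiency=efficiency,
            qc_pass=True,
        )
        for i, row in enumerate(calls_rows)
    ]


@pytest.fixture
def flat_profile():
    def _make(n_cpg: int, p: float, region="FOXP3_TSDR", strand="top", mode="independent"):
        return MethylationProfile(
            region=region, strand=strand, p_meth=(p,) * n_cpg, correlation_mode=mode
        )

    return _make
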