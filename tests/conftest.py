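import numpy as np
import pytest

from regulonscan import SiteAlignment, build_matrix
from regulonscan.simulate import DEFAULT_DR_CONSENSUS


@pytest.fixture(scope="session")
def toy_alignment():
    """Counts {A:3,C:1}, {G:4}, {T:2,A:2} — hand-checkable."""
    return SiteAlignment(("AGT", "AGT", "AGA", "CGA"))


@pytest.fixture(scope="session")
def dr_alignment():
    """A slightly degenerate 10-bp half-site alignment (n=12)."""
    variants = (
        DEFAULT_DR_CONSENSUS,
        DEFAULT_DR_CONSENSUS,
        DEFAULT_DR_CONSENSUS,
        DEFAULT_DR_CONSENSUS,
        DEFAULT_DR_CONSENSUS,
        DEFAULT_DR_CONSENSUS,
        "TGTTAATAAA",
        "TGTTAACTAA",
        "TGCTAATTAA",
        "AGTTAATTAA",
        "TGTTGATTAA",
        "TGTTAATTAC",
    )
    return SiteAlignment(variants)


@pytest.fixture(scope="session")
def dr_matrix(dr_alignment):
    return build_matrix(dr_alignment, pseudocount=0.25)


@pytest.fixture(scope="session")
def box_alignment(dr_alignment):
    """21-column box alignment: DR + 1-bp spacer + DR + 1 trailing bp.

    Columns cover motif positions -3..+17 (offset 3) so both half-site
    frames (-3..+6 and +8..+17) are present.
    """
    rng = np.random.default_rng(42)
    spacers = rng.choice(list("ACGT"), size=(len(dr_alignment.sequences), 1))
    seqs = tuple(
        s + sp[0] + s2
        for (s, s2), sp in zip(
            zip(dr_alignment.sequences, dr_alignment.sequences[::-1]),
            spacers,
        )
    )
    return SiteAlignment(seqs, offset=3)
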