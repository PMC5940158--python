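import pytest

from scramblekit.arrangements import MdsRecord
from scramblekit.simulate import LocusSpec, realize


@pytest.fixture
def fig1a_records() -> list[MdsRecord]:
    """Three-colour nested architecture: a scrambled odd-even locus (red)
    hosts a scrambled locus (blue, pointer word 12341243) in one IES,
    which hosts a nonscrambled three-MDS locus (orange)."""
    orange = LocusSpec("orange", "M1 M2 M3")
    blue = LocusSpec("blue", "M1 M3 M5 M2 -M4", children={1: [orange]})
    red = LocusSpec("red", "M1 M3 M5 M7 -M6 -M4 -M2", children={2: [blue]})
    return realize("mic_fig1a", [red])


@pytest.fixture
def fig2_records() -> list[MdsRecord]:
    """Three layers of nesting on one MIC contig: red > blue > orange."""
    orange = LocusSpec("Contig6683.0", "M1 M2")
    blue = LocusSpec("Contig9583.0", "M1 M2 M3", children={0: [orange]})
    red = LocusSpec("Contig6331.0", "M1 M2 M3 M4", children={1: [blue]})
    return realize("ctg7180000067077", [red])


@pytest.fixture
def doll_chain_records():
    """Factory: strict Russian-doll chain of the given depth; layer ids
    are doll0 (outermost) .. doll<d> (innermost)."""

    def build(depth: int) -> list[MdsRecord]:
        spec = None
        for layer in range(depth, -1, -1):
            children = {0: [spec]} if spec is not None else {}
            spec = LocusSpec(f"doll{layer}", "M1 M2 M3", children=children)
        return realize("mic_chain", [spec])

    return build


@pytest.fixture
def interleaved_records() -> list[MdsRecord]:
    """Two loci with alternating MDSs: A1 B1 A2 B2."""
    rows = []
    pos = 1
    for mac, idx in (("A", 1), ("B", 1), ("A", 2), ("B", 2)):
        rows.append(MdsRecord("mic_ilv", mac, idx, pos, pos + 99, "+"))
        pos += 150
    return rows
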