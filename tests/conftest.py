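import itertools

import numpy as np
import pytest

from mipscan.patterns import MotifPattern, PatternElement, load_registry
from mipscan.seqio import SequenceRecord

ALPHA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def registry():
    return load_registry()


def make_record(residues: str, rid: str = "seq") -> SequenceRecord:
    return SequenceRecord(id=rid, residues=residues)


def random_pattern(rng: np.random.Generator, max_elements: int = 6) -> MotifPattern:
    """Small random grammar for oracle-equivalence testing."""
    n = int(rng.integers(1, max_elements + 1))
    elements = []
    for _ in range(n):
        if rng.random() < 0.55:
            k = int(rng.integers(1, 5))
            allowed = frozenset(rng.choice(list(ALPHA), size=k, replace=False))
            elements.append(PatternElement(kind="residue-class", allowed=allowed))
        else:
            lo = int(rng.integers(0, 4))
            hi = lo + int(rng.integers(0, 4))
            elements.append(PatternElement(kind="wildcard-gap", min_len=lo, max_len=hi))
    # ensure at least one residue class so the pattern is not pure wildcard
    if all(e.kind == "wildcard-gap" for e in elements):
        elements.append(PatternElement(kind="residue-class", allowed=frozenset("A")))
    syntax = "-".join(
        "[" + "".join(sorted(e.allowed)) + "]" if e.kind == "residue-class"
        else f"X({e.min_len},{e.max_len})"
        for e in elements
    )
    return MotifPattern(name="rand", syntax=syntax, elements=tuple(elements))


def brute_force_scan(seq: str, pattern: MotifPattern) -> set[tuple[int, int]]:
    """Independent oracle: test every (start, gap-assignment) combination.

    Returns the set of 1-based inclusive (start, end) matching windows.
    """
    gap_ranges = [
        range(e.min_len, e.max_len + 1) if e.kind == "wildcard-gap" else range(1, 2)
        for e in pattern.elements
    ]
    found: set[tuple[int, int]] = set()
    for start in range(len(seq)):
        for lens in itertools.product(*gap_ranges):
            pos = start
            ok = True
            for e, k in zip(pattern.elements, lens):
                if pos + k > len(seq):
                    ok = False
                    break
                if e.kind == "residue-class":
                    if seq[pos] not in e.allowed:
                        ok = False
                        break
                pos += k
            if ok:
                found.add((start + 1, pos))
    return found
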