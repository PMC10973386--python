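"""Seeded synthetic proteomes with implanted motifs and exact ground truth.

Every pipeline stage is testable without downloads: i.i.d. background
sequences, single-motif implants at controlled per-position divergence,
tandem arrays with fixed unit length, full family-architecture benchmarks
with 1:1 decoys, and the analytic false-positive expectation for a grammar
on random background.

All randomness flows through one ``numpy.random.Generator`` derived from an
explicit integer seed; identical seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._alphabet import CANONICAL
from .patterns import MotifPattern, load_registry, scan
from .module_caller import ModuleCallerConfig, call_modules
from .seqio import SequenceRecord

#: family benchmark recipes (the fixture-driven DM10 family is excluded:
#: its folded PH-like domain is beyond motif-grammar reach)
RECIPES = (
    "NWE + Mn",
    "NWE only",
    "Mn repeat (only)",
    "Mn + PYG",
    "PYG",
    "SNYG",
    "GFG repeat",
    "ELLEn",
)

_RETRY_CAP = 1000


@dataclass(frozen=True)
class TruthAnnotation:
    """Ground-truth interval of one implanted motif copy (1-based inclusive)."""

    sequence_id: str
    pattern_name: str
    start: int
    end: int
    divergence_applied: float
    copy_index: int = 0


@dataclass
class ImplantSpec:
    """What to implant: a registry grammar or an explicit consensus string."""

    pattern_name: Optional[str] = None
    consensus: Optional[str] = None
    count: int = 1
    divergence: float = 0.0
    placement: Union[str, Sequence[int]] = "random-nonoverlapping"
    tandem_copies: Optional[int] = None
    unit_spacing: Optional[int] = None
    preserve_match: bool = True

    def __post_init__(self) -> None:
        if (self.pattern_name is None) == (self.consensus is None):
            raise ValueError("give exactly one of pattern_name or consensus")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must lie in [0, 1)")


def generate_background(
    length: int,
    frequencies: Optional[np.ndarray] = None,
    seed: Union[int, np.random.Generator] = 0,
    record_id: str = "background",
) -> SequenceRecord:
    """Seeded i.i.d. residue string over the canonical alphabet."""
    if length < 0:
        raise ValueError("length must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if frequencies is None:
        freqs = np.full(20, 0.05)
    else:
        freqs = np.asarray(frequencies, dtype=float)
        if freqs.shape != (20,) or np.any(freqs < 0) or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("frequencies must be 20 non-negative values summing to 1")
    letters = rng.choice(list(CANONICAL), size=length, p=freqs)
    return SequenceRecord(id=record_id, residues="".join(letters))


def sample_pattern_instance(
    pattern: MotifPattern,
    rng: np.random.Generator,
    gap_mode: str = "shortest",
) -> tuple[str, list[Optional[frozenset]]]:
    """One concrete string satisfying *pattern*.

    Residue-class members are drawn uniformly; gaps take their minimum length
    (``gap_mode="shortest"``, the default) or a uniform length in range
    (``"uniform"``), filled with uniform canonical residues.  Also returns,
    per emitted position, the residue class it instantiates (None for gap
    positions) so divergence can respect class membership.
    """
    chars: list[str] = []
    classes: list[Optional[frozenset]] = []
    for el in pattern.elements:
        if el.kind == "residue-class":
            chars.append(rng.choice(sorted(el.allowed)))
            classes.append(el.allowed)
        else:
            if gap_mode == "shortest":
                k = el.min_len
            elif gap_mode == "uniform":
                k = int(rng.integers(el.min_len, el.max_len + 1))
            else:
                raise ValueError(f"unknown gap_mode {gap_mode!r}")
            for _ in range(k):
                chars.append(rng.choice(list(CANONICAL)))
                classes.append(None)
    return "".join(chars), classes


def _mutate(
    instance: str,
    classes: Sequence[Optional[frozenset]],
    divergence: float,
    preserve_match: bool,
    rng: np.random.Generator,
) -> str:
    out = list(instance)
    for i, ch in enumerate(out):
        if rng.random() >= divergence:
            continue
        cls = classes[i] if preserve_match else None
        if cls is not None and len(cls) > 1:
            choices = sorted(cls - {ch})
        elif cls is not None:
            continue  # single-residue class with preserve_match: nothing to do
        else:
            choices = [c for c in CANONICAL if c != ch]
        out[i] = rng.choice(choices)
    return "".join(out)


def implant(
    host: SequenceRecord,
    spec: ImplantSpec,
    seed: Union[int, np.random.Generator] = 0,
    registry: Optional[dict[str, MotifPattern]] = None,
) -> tuple[SequenceRecord, list[TruthAnnotation]]:
    """Write motif instances into *host* and record their true intervals.

    Placement is non-overlapping; random placement retries up to a cap before
    raising.  With ``tandem_copies`` the unit is laid down that many times,
    successive unit starts separated by ``unit_spacing`` (default: the unit
    length, i.e. contiguous tandem).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.pattern_name is not None:
        reg = registry or load_registry()
        pattern = reg[spec.pattern_name]
        name = spec.pattern_name
        unit, classes = sample_pattern_instance(pattern, rng)
    else:
        unit = spec.consensus.upper()
        classes = [None] * len(unit)
        name = "consensus"
    copies = spec.tandem_copies or 1
    spacing = spec.unit_spacing or len(unit)
    if spacing < len(unit):
        raise ValueError("unit_spacing must be at least the unit length")
    footprint = spacing * (copies - 1) + len(unit)

    residues = list(host.residues)
    occupied: list[tuple[int, int]] = []  # 0-based [start, end) of prior implants
    truths: list[TruthAnnotation] = []

    if isinstance(spec.placement, str):
        if spec.placement != "random-nonoverlapping":
            raise ValueError(f"unknown placement {spec.placement!r}")
        starts = None
    else:
        starts = [p - 1 for p in spec.placement]  # user gives 1-based
        if len(starts) != spec.count:
            raise ValueError("fixed placement needs one position per implant")

    for imp in range(spec.count):
        if starts is not None:
            s0 = starts[imp]
            if s0 < 0 or s0 + footprint > len(residues):
                raise ValueError(f"fixed implant at {s0 + 1} does not fit host")
            if any(s0 < e and b < s0 + footprint for b, e in occupied):
                raise ValueError("fixed implants overlap")
        else:
            if footprint > len(residues):
                raise ValueError("implant footprint exceeds host length")
            for attempt in range(_RETRY_CAP):
                s0 = int(rng.integers(0, len(residues) - footprint + 1))
                if not any(s0 < e and b < s0 + footprint for b, e in occupied):
                    break
            else:
                raise RuntimeError(f"no non-overlapping placement found in {_RETRY_CAP} tries")
        occupied.append((s0, s0 + footprint))
        for c in range(copies):
            mutated = _mutate(unit, classes, spec.divergence, spec.preserve_match, rng)
            u0 = s0 + c * spacing
            residues[u0:u0 + len(unit)] = mutated
            truths.append(
                TruthAnnotation(
                    sequence_id=host.id,
                    pattern_name=name,
                    start=u0 + 1,
                    end=u0 + len(unit),
                    divergence_applied=spec.divergence,
                    copy_index=c,
                )
            )
    return SequenceRecord(id=host.id, residues="".join(residues),
                          description=host.description), truths


def expected_matches_per_position(pattern: MotifPattern) -> float:
    """Analytic expected matches per start on uniform background.

    Product of class probabilities (|class|/20) times the number of distinct
    gap-length assignments; counts (start, end) match pairs as the
    all-overlapping scanner does.
    """
    prob = 1.0
    combos = 1
    for el in pattern.elements:
        if el.kind == "residue-class":
            prob *= len(el.allowed) / 20.0
        else:
            combos *= el.max_len - el.min_len + 1
    return prob * combos


_HYDROPHOBIC = "LIV"  # strong Kyte-Doolittle positives for SNYG flanks


def _clean_host(length: int, rng: np.random.Generator,
                registry: dict[str, MotifPattern],
                config: ModuleCallerConfig, record_id: str) -> SequenceRecord:
    """Background sequence verified to carry no module-family signal.

    Rejection-sampled so that ground truth is exact: a 'decoy' or implant
    host contains no chance family-level architecture (isolated single motif
    hits may remain; they do not reach a family label)."""
    for attempt in range(_RETRY_CAP):
        host = generate_background(length, seed=rng, record_id=record_id)
        _, fam = call_modules(host, registry, config)
        if fam.family_label == "unassigned":
            return host
    raise RuntimeError("could not generate an unassigned background host")


def _recipe_layout(recipe: str, rng: np.random.Generator,
                   registry: dict[str, MotifPattern], divergence: float,
                   host: SequenceRecord) -> tuple[SequenceRecord, list[TruthAnnotation]]:
    """Implant one family architecture into a clean host."""
    seq = host
    truths: list[TruthAnnotation] = []

    def put(pattern_name: str, positions: list[int], spacing: Optional[int] = None,
            copies: Optional[int] = None) -> None:
        nonlocal seq, truths
        for pos in positions:
            spec = ImplantSpec(pattern_name=pattern_name, divergence=divergence,
                               placement=[pos], count=1,
                               tandem_copies=copies, unit_spacing=spacing)
            seq, t = implant(seq, spec, seed=rng, registry=registry)
            truths.extend(t)

    L = len(seq)
    base = int(rng.integers(20, max(21, L - 160)))
    if recipe == "NWE + Mn":
        put("NWE", [base])
        put("MN_UNIT", [base + 20, base + 40])
    elif recipe == "NWE only":
        put("NWE", [base])
    elif recipe == "Mn repeat (only)":
        put("MN_UNIT", [base, base + 16, base + 32, base + 48])
    elif recipe == "Mn + PYG":
        put("MN_UNIT", [base, base + 16])
        pyg_base = base + 16 + 61  # beyond the chaining gap of the Mn array
        put("PYG", [pyg_base, pyg_base + 25, pyg_base + 50])
    elif recipe == "PYG":
        put("PYG", [base, base + 25, base + 50])
    elif recipe == "GFG repeat":
        put("GFG", [base, base + 31, base + 62, base + 93])
    elif recipe == "SNYG":
        put("SNYG", [base])
        motif = truths[-1]
        res = list(seq.residues)
        for i in range(motif.start - 5, motif.start - 1):
            res[i] = rng.choice(list(_HYDROPHOBIC))
        for i in range(motif.end, motif.end + 4):
            res[i] = rng.choice(list(_HYDROPHOBIC))
        seq = SequenceRecord(id=seq.id, residues="".join(res))
    elif recipe == "ELLEn":
        put("ELLEN", [base])
    else:
        raise ValueError(f"unknown recipe {recipe!r}; known: {RECIPES}")
    return seq, truths


#: expected array copy counts per recipe (architecture verification)
_EXPECTED_ARCH = {
    "NWE + Mn": {"NWE_TRIAD": 1},
    "NWE only": {"NWE_ONLY": 1},
    "Mn repeat (only)": {"MN_ARRAY": (1, 4)},
    "Mn + PYG": {"MN_ARRAY": (1, 2), "PYG_ARRAY": (1, 3)},
    "PYG": {"PYG_ARRAY": (1, 3)},
    "SNYG": {"SNYG_MODULE": 1},
    "GFG repeat": {"GFG_ARRAY": (1, 4)},
    "ELLEn": {"ELLEN": 1},
}


def _architecture_ok(seq: SequenceRecord, recipe: str,
                     registry: dict[str, MotifPattern],
                     config: ModuleCallerConfig) -> bool:
    """Exact-architecture check used at zero divergence: the intended family
    label must be called and each expected module must appear once with the
    implanted copy count (chance background hits can otherwise inflate or
    split arrays)."""
    calls, fam = call_modules(seq, registry, config)
    if fam.family_label != recipe:
        return False
    for mtype, want in _EXPECTED_ARCH[recipe].items():
        of_type = [c for c in calls if c.module_type == mtype]
        if isinstance(want, tuple):
            n_calls, copies = want
            if len(of_type) != n_calls or any(c.copy_count != copies for c in of_type):
                return False
        elif len(of_type) != want:
            return False
    return True


def generate_family_benchmark(
    recipe: str,
    n_proteins: int = 20,
    divergence: float = 0.0,
    seed: int = 0,
    host_length: int = 300,
    registry: Optional[dict[str, MotifPattern]] = None,
    config: Optional[ModuleCallerConfig] = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Family-architecture benchmark: *n_proteins* positives plus as many decoys.

    Positives instantiate the recipe's module architecture at the requested
    divergence; decoys are module-free background of the same length.  The
    returned truth table has one row per implanted motif copy plus one
    ``role`` row per sequence giving the intended family label.
    """
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; known: {RECIPES}")
    rng = np.random.default_rng(seed)
    reg = registry or load_registry()
    cfg = config or ModuleCallerConfig()
    records: list[SequenceRecord] = []
    rows: list[dict] = []
    slug = recipe.replace(" ", "_").replace("(", "").replace(")", "").replace("+", "plus")
    for i in range(n_proteins):
        rid = f"{slug}_pos_{i:03d}"
        for attempt in range(_RETRY_CAP):
            host = _clean_host(host_length, rng, reg, cfg, rid)
            seq, truths = _recipe_layout(recipe, rng, reg, divergence, host)
            # at zero divergence the labels are guaranteed, so reject layouts
            # where chance background hits distort the intended architecture
            if divergence > 0 or _architecture_ok(seq, recipe, reg, cfg):
                break
        else:
            raise RuntimeError(f"could not realize architecture for {recipe!r}")
        records.append(seq)
        for t in truths:
            rows.append(
                {
                    "sequence_id": t.sequence_id,
                    "pattern_name": t.pattern_name,
                    "start": t.start,
                    "end": t.end,
                    "divergence_applied": t.divergence_applied,
                    "copy_index": t.copy_index,
                    "role": "positive",
                    "intended_label": recipe,
                }
            )
    for i in range(n_proteins):
        rid = f"{slug}_decoy_{i:03d}"
        decoy = _clean_host(host_length, rng, reg, cfg, rid)
        records.append(decoy)
        rows.append(
            {
                "sequence_id": rid,
                "pattern_name": "",
                "start": 0,
                "end": 0,
                "divergence_applied": 0.0,
                "copy_index": -1,
                "role": "decoy",
                "intended_label": "unassigned",
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["sequence_id", "pattern_name", "start", "end",
                 "divergence_applied", "copy_index", "role", "intended_label"],
    )
    return records, truth
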