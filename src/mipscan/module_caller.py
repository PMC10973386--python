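"""Composite module calling and family assignment.

Individual motif matches are combined into the composite microtubule-binding
modules of the MIP families: the NWE triad (an NWE motif followed by two Mn
repeat units within ~100 residues), tandem arrays of Mn/PYG/GFG units, the
SNYG module (a divergent Mn-like motif flanked by short hydrophobic
stretches), and the long ELLEn module.  A deterministic precedence then maps
each protein's call multiset onto a family row label.

The hydrophobic-flank test for SNYG uses the Kyte-Doolittle hydropathy scale
(via Biopython); it replaces secondary-structure prediction of the associated
helix with a sequence-only heuristic, which is the deliberate desk-scale
simplification of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .patterns import MotifMatch, MotifPattern, scan

MODULE_TYPES = (
    "NWE_TRIAD",
    "NWE_ONLY",
    "SNYG_MODULE",
    "SNYG_CANDIDATE",
    "PYG_ARRAY",
    "GFG_ARRAY",
    "MN_ARRAY",
    "ELLEN",
    "MN_UNIT_ISOLATED",
)

#: family row labels produced by :func:`assign_family`
FAMILY_LABELS = (
    "NWE + Mn",
    "NWE only",
    "Mn + PYG",
    "Mn repeat (only)",
    "PYG",
    "GFG repeat",
    "SNYG",
    "ELLEn",
    "unassigned",
)


@dataclass(frozen=True)
class ModuleCall:
    """A composite module on one protein; region 1-based inclusive."""

    sequence_id: str
    module_type: str
    region: tuple[int, int]
    component_matches: tuple[MotifMatch, ...] = ()
    copy_count: int = 0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.module_type not in MODULE_TYPES:
            raise ValueError(f"unknown module type {self.module_type!r}")
        for m in self.component_matches:
            if not (self.region[0] <= m.start and m.end <= self.region[1]):
                raise ValueError("module region must cover all component matches")


@dataclass(frozen=True)
class FamilyAssignment:
    sequence_id: str
    family_label: str
    secondary_labels: tuple[str, ...] = ()


@dataclass
class ModuleCallerConfig:
    """Tunable thresholds for composite calling (defaults documented in docs)."""

    max_module_span: int = 100       # NWE triad total span bound, residues
    array_min_copies: int = 2        # minimum units in a tandem array call
    max_inter_gap: int = 60          # max start-to-start spacing within an array
    snyg_flank_window: int = 4       # residues per hydrophobic flank
    snyg_hydropathy_threshold: float = 1.5  # min mean Kyte-Doolittle per flank


_ARRAY_TYPE = {"MN_UNIT": "MN_ARRAY", "PYG": "PYG_ARRAY", "GFG": "GFG_ARRAY"}


def call_nwe_module(
    nwe_matches: Sequence[MotifMatch],
    mn_matches: Sequence[MotifMatch],
    max_module_span: int = 100,
) -> list[ModuleCall]:
    """Call NWE triads (NWE motif + two downstream Mn units) or bare NWE motifs.

    For each NWE match (left to right) the first two not-yet-used Mn matches
    starting after the NWE motif are taken; if the full span from NWE start to
    the second Mn end is within *max_module_span*, an ``NWE_TRIAD`` is
    emitted, else (or with fewer than two Mn units available) ``NWE_ONLY``.
    """
    calls: list[ModuleCall] = []
    mn_sorted = sorted(mn_matches, key=lambda m: (m.start, m.end))
    used: set[int] = set()
    for nwe in sorted(nwe_matches, key=lambda m: (m.start, m.end)):
        downstream = [
            (i, m) for i, m in enumerate(mn_sorted)
            if i not in used and m.start > nwe.end
        ]
        if len(downstream) >= 2:
            (i1, mn1), (i2, mn2) = downstream[0], downstream[1]
            span = mn2.end - nwe.start + 1
            if span <= max_module_span:
                used.update((i1, i2))
                calls.append(
                    ModuleCall(
                        sequence_id=nwe.sequence_id,
                        module_type="NWE_TRIAD",
                        region=(nwe.start, mn2.end),
                        component_matches=(nwe, mn1, mn2),
                    )
                )
                continue
        calls.append(
            ModuleCall(
                sequence_id=nwe.sequence_id,
                module_type="NWE_ONLY",
                region=(nwe.start, nwe.end),
                component_matches=(nwe,),
            )
        )
    return calls


def consumed_mn(calls: Iterable[ModuleCall]) -> set[MotifMatch]:
    """Mn matches absorbed into NWE triads (to exclude from array calling)."""
    out: set[MotifMatch] = set()
    for c in calls:
        if c.module_type == "NWE_TRIAD":
            out.update(c.component_matches[1:])
    return out


def call_repeat_array(
    matches: Sequence[MotifMatch],
    min_copies: int = 2,
    max_inter_gap: int = 60,
) -> list[ModuleCall]:
    """Chain same-pattern matches into tandem array calls.

    Maximal chains of matches whose successive start-to-start gaps are at most
    *max_inter_gap* become one ``*_ARRAY`` call with ``copy_count`` equal to
    the chain length; shorter chains yield no array call.
    """
    arrays: list[ModuleCall] = []
    ms = sorted(matches, key=lambda m: (m.start, m.end))
    i = 0
    while i < len(ms):
        chain = [ms[i]]
        j = i + 1
        while j < len(ms) and ms[j].start - chain[-1].start <= max_inter_gap:
            chain.append(ms[j])
            j += 1
        if len(chain) >= min_copies:
            pattern = chain[0].pattern_name
            arrays.append(
                ModuleCall(
                    sequence_id=chain[0].sequence_id,
                    module_type=_ARRAY_TYPE.get(pattern, "MN_ARRAY"),
                    region=(chain[0].start, chain[-1].end),
                    component_matches=tuple(chain),
                    copy_count=len(chain),
                )
            )
        i = j
    return arrays


def _flank_hydropathy(residues: str, lo: int, hi: int) -> tuple[Optional[float], bool]:
    """Mean Kyte-Doolittle over 1-based inclusive [lo, hi] clipped to the sequence.

    Returns (mean or None when the clipped window is empty, truncated?).
    """
    lo_c, hi_c = max(lo, 1), min(hi, len(residues))
    truncated = (lo_c != lo) or (hi_c != hi)
    window = residues[lo_c - 1:hi_c]
    values = [KYTE_DOOLITTLE[c] for c in window if c in KYTE_DOOLITTLE]
    if not values:
        return None, truncated
    return sum(values) / len(values), truncated


def call_snyg_module(
    snyg_matches: Sequence[MotifMatch],
    sequence,
    flank_window: int = 4,
    hydropathy_threshold: float = 1.5,
) -> list[ModuleCall]:
    """Promote SNYG motif matches with hydrophobic flanks to module calls.

    Both flanking windows must have mean Kyte-Doolittle hydropathy at or above
    the threshold; motifs without such flanks are reported as
    ``SNYG_CANDIDATE``.  Windows truncated by a sequence terminus are
    evaluated on the available residues and flagged ``truncated_flank``.
    """
    calls: list[ModuleCall] = []
    res = sequence.residues
    for m in sorted(snyg_matches, key=lambda x: (x.start, x.end)):
        left, ltrunc = _flank_hydropathy(res, m.start - flank_window, m.start - 1)
        right, rtrunc = _flank_hydropathy(res, m.end + 1, m.end + flank_window)
        flags = ("truncated_flank",) if (ltrunc or rtrunc) else ()
        means = [v for v in (left, right) if v is not None]
        hydrophobic = bool(means) and all(v >= hydropathy_threshold for v in means)
        calls.append(
            ModuleCall(
                sequence_id=m.sequence_id,
                module_type="SNYG_MODULE" if hydrophobic else "SNYG_CANDIDATE",
                region=(m.start, m.end),
                component_matches=(m,),
                flags=flags,
            )
        )
    return calls


#: precedence order for the primary family label
_PRECEDENCE = (
    ("NWE_TRIAD", "NWE + Mn"),
    ("NWE_ONLY", "NWE only"),
    (("MN_ARRAY", "PYG_ARRAY"), "Mn + PYG"),
    ("MN_ARRAY", "Mn repeat (only)"),
    ("PYG_ARRAY", "PYG"),
    ("GFG_ARRAY", "GFG repeat"),
    ("SNYG_MODULE", "SNYG"),
    ("ELLEN", "ELLEn"),
)


def assign_family(calls: Sequence[ModuleCall], sequence_id: Optional[str] = None) -> FamilyAssignment:
    """Map one protein's module calls onto a family row label.

    Pure function of the call multiset (input order is irrelevant); the first
    satisfied precedence rule gives the primary label and every other
    satisfied rule is listed as a secondary label.
    """
    if sequence_id is None:
        sequence_id = calls[0].sequence_id if calls else "<unknown>"
    types = {c.module_type for c in calls}
    satisfied: list[str] = []
    for key, label in _PRECEDENCE:
        needed = key if isinstance(key, tuple) else (key,)
        if all(k in types for k in needed):
            satisfied.append(label)
    if not satisfied:
        return FamilyAssignment(sequence_id, "unassigned")
    primary = satisfied[0]
    secondary = tuple(
        lab for lab in satisfied[1:]
        # "Mn + PYG" subsumes its two single-module labels
        if not (primary == "Mn + PYG" and lab in ("Mn repeat (only)", "PYG"))
    )
    return FamilyAssignment(sequence_id, primary, secondary)


def call_modules(
    sequence,
    registry: dict[str, MotifPattern],
    config: Optional[ModuleCallerConfig] = None,
) -> tuple[list[ModuleCall], FamilyAssignment]:
    """Scan one protein with every registry grammar and call composite modules."""
    cfg = config or ModuleCallerConfig()
    matches = {
        name: scan(sequence, pat, mode="leftmost-nonoverlapping")
        for name, pat in registry.items()
    }
    calls: list[ModuleCall] = []

    nwe_calls = call_nwe_module(
        matches.get("NWE", []), matches.get("MN_UNIT", []), cfg.max_module_span
    )
    calls.extend(nwe_calls)
    taken = consumed_mn(nwe_calls)
    free_mn = [m for m in matches.get("MN_UNIT", []) if m not in taken]

    mn_arrays = call_repeat_array(free_mn, cfg.array_min_copies, cfg.max_inter_gap)
    calls.extend(mn_arrays)
    in_arrays = {m for a in mn_arrays for m in a.component_matches}
    for m in free_mn:
        if m not in in_arrays:
            calls.append(
                ModuleCall(sequence.id, "MN_UNIT_ISOLATED", (m.start, m.end), (m,))
            )

    for name in ("PYG", "GFG"):
        calls.extend(
            call_repeat_array(matches.get(name, []), cfg.array_min_copies, cfg.max_inter_gap)
        )

    calls.extend(
        call_snyg_module(
            matches.get("SNYG", []), sequence,
            cfg.snyg_flank_window, cfg.snyg_hydropathy_threshold,
        )
    )

    for m in matches.get("ELLEN", []):
        calls.append(ModuleCall(sequence.id, "ELLEN", (m.start, m.end), (m,)))

    return calls, assign_family(calls, sequence.id)


def calls_to_rows(calls: Sequence[ModuleCall]) -> list[dict]:
    return [
        {
            "sequence_id": c.sequence_id,
            "module_type": c.module_type,
            "start": c.region[0],
            "end": c.region[1],
            "copy_count": c.copy_count,
            "n_components": len(c.component_matches),
            "flags": ",".join(c.flags),
        }
        for c in calls
    ]


def calls_to_gff3(calls: Sequence[ModuleCall], source: str = "mipscan") -> str:
    lines = ["##gff-version 3"]
    for c in calls:
        attrs = f"Name={c.module_type}"
        if c.copy_count:
            attrs += f";copy_count={c.copy_count}"
        lines.append(
            "\t".join(
                [c.sequence_id, source, "module", str(c.region[0]), str(c.region[1]),
                 ".", ".", ".", attrs]
            )
        )
    return "\n".join(lines) + "\n"
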