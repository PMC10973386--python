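"""Reciprocal-search validation of remote-homology hits.

A forward hit (query -> target) is considered reliable only when the forward
E-value clears the cutoff AND the target, used as a reciprocal search query,
recovers the original query (or, optionally, any member of the query's family)
below the same cutoff.  Both comparisons are strict: E < cutoff, default 0.01.
Every verdict carries a machine-readable reason code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

DEFAULT_E_CUTOFF = 0.01

REASONS = (
    "passed",
    "forward_above_cutoff",
    "no_reciprocal_search",
    "reciprocal_missed_query",
)


@dataclass(frozen=True)
class HitRecord:
    """One homology search hit: query matched target with the given E-value."""

    query: str
    target: str
    evalue: float
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.evalue > 0):
            raise ValueError(
                f"E-value must be positive, got {self.evalue!r} for {self.query}->{self.target}"
            )


@dataclass(frozen=True)
class ReciprocalVerdict:
    query: str
    target: str
    forward_evalue: float
    reciprocal_evalue: Optional[float]
    reliable: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason code {self.reason!r}")
        if self.reliable and self.reason != "passed":
            raise ValueError("reliable verdicts must carry reason 'passed'")


def reciprocal_validate(
    forward: Sequence[HitRecord],
    reciprocals: Mapping[str, Sequence[HitRecord]],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    family_of: Optional[Mapping[str, str]] = None,
) -> list[ReciprocalVerdict]:
    """Apply the two-condition reciprocal reliability rule to forward hits.

    *reciprocals* maps each target id to the hit table obtained when that
    target was used as a search query.  When *family_of* is supplied,
    recapitulation is satisfied by any protein sharing the original query's
    family; by default the original query itself must be recovered.
    """
    verdicts: list[ReciprocalVerdict] = []
    for hit in forward:
        if not hit.evalue < e_cutoff:
            verdicts.append(
                ReciprocalVerdict(hit.query, hit.target, hit.evalue, None, False,
                                  "forward_above_cutoff")
            )
            continue
        if hit.target not in reciprocals:
            verdicts.append(
                ReciprocalVerdict(hit.query, hit.target, hit.evalue, None, False,
                                  "no_reciprocal_search")
            )
            continue
        recap = _recapitulation(hit.query, reciprocals[hit.target], e_cutoff, family_of)
        if recap is None:
            verdicts.append(
                ReciprocalVerdict(hit.query, hit.target, hit.evalue, None, False,
                                  "reciprocal_missed_query")
            )
        else:
            verdicts.append(
                ReciprocalVerdict(hit.query, hit.target, hit.evalue, recap, True, "passed")
            )
    return verdicts


def _recapitulation(
    query: str,
    reciprocal_hits: Sequence[HitRecord],
    e_cutoff: float,
    family_of: Optional[Mapping[str, str]],
) -> Optional[float]:
    """Best reciprocal E-value recovering *query* (or its family), else None."""
    accept: set[str] = {query}
    if family_of is not None and query in family_of:
        fam = family_of[query]
        accept.update(pid for pid, f in family_of.items() if f == fam)
    best = None
    for rh in reciprocal_hits:
        if rh.target in accept and rh.evalue < e_cutoff:
            if best is None or rh.evalue < best:
                best = rh.evalue
    return best


def summarize_reliable(
    verdicts: Iterable[ReciprocalVerdict],
    species_of: Mapping[str, str],
) -> dict[str, int]:
    """Count distinct reliable targets per species.

    Targets missing from *species_of* are tallied under ``"unknown"``.
    """
    seen: dict[str, set[str]] = {}
    for v in verdicts:
        if not v.reliable:
            continue
        sp = species_of.get(v.target, "unknown")
        seen.setdefault(sp, set()).add(v.target)
    return {sp: len(targets) for sp, targets in sorted(seen.items())}


def verdicts_to_rows(verdicts: Iterable[ReciprocalVerdict]) -> list[dict]:
    """Verdicts as plain dicts, ready for a TSV writer."""
    return [
        {
            "query": v.query,
            "target": v.target,
            "forward_evalue": v.forward_evalue,
            "reciprocal_evalue": "" if v.reciprocal_evalue is None else v.reciprocal_evalue,
            "reliable": int(v.reliable),
            "reason": v.reason,
        }
        for v in verdicts
    ]
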