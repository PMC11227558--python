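"""Sequence-context annotation of protospacers.

rAPOBEC1-based editors discriminate against a 5'-GC dinucleotide at the edit
site and lose activity on very GC-rich protospacers, so each candidate is
annotated with: GC content of the 20-mer, presence of a GC motif whose C
falls inside the editing window, the count of bystander Cs in the window,
and the PAM class (NGA/NGT/NGC/NGG/other).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from cbestop.scanner import EditingWindow, Protospacer, SPACER_LEN, ScanError


@dataclass(frozen=True)
class ContextAnnotation:
    gc_percent: float
    gc_motif_in_window: bool
    bystander_c_count: int
    pam_class: str


def gc_content(spacer: str) -> float:
    """GC percentage of the 20-mer spacer (PAM excluded): 100 * (G+C) / 20."""
    if len(spacer) != SPACER_LEN:
        raise ScanError(f"spacer length {len(spacer)} != {SPACER_LEN}")
    return 100.0 * (spacer.count("G") + spacer.count("C")) / SPACER_LEN


def has_gc_motif(spacer: str, window: EditingWindow, require_g_in_window: bool = False) -> bool:
    """True when some window position p holds a C preceded by a G.

    Only the C must lie inside the window; the G may sit at window.first - 1
    (the deaminase context is the 5' neighbour of the edited C). Position 1
    never qualifies since it has no 5' neighbour within the spacer. Setting
    ``require_g_in_window`` demands both bases in-window instead.
    """
    if len(spacer) != SPACER_LEN:
        raise ScanError(f"spacer length {len(spacer)} != {SPACER_LEN}")
    lo = window.first + 1 if require_g_in_window else max(window.first, 2)
    for p in range(lo, window.last + 1):
        if spacer[p - 1] == "C" and spacer[p - 2] == "G":
            return True
    return False


def bystander_c_count(spacer: str, window: EditingWindow, target_c_pos: int) -> int:
    """Number of window Cs other than the target C."""
    if target_c_pos not in window:
        raise ScanError(f"target position {target_c_pos} outside window {window}")
    if spacer[target_c_pos - 1] != "C":
        raise ScanError(f"spacer position {target_c_pos} is {spacer[target_c_pos - 1]}, not C")
    return sum(
        1 for p in window.positions() if p != target_c_pos and spacer[p - 1] == "C"
    )


def pam_class(pam: str) -> str:
    """NGA/NGT/NGC/NGG when the middle base is G, else "other"."""
    if len(pam) != 3:
        raise ScanError(f"PAM length {len(pam)} != 3")
    return f"NG{pam[2]}" if pam[1] == "G" else "other"


def annotate(
    protospacers: Iterable[Protospacer],
    window: EditingWindow,
    require_g_in_window: bool = False,
) -> list[Protospacer]:
    """Attach a :class:`ContextAnnotation` to each protospacer, in place."""
    out = []
    for p in protospacers:
        p.annotation = ContextAnnotation(
            gc_percent=gc_content(p.spacer),
            gc_motif_in_window=has_gc_motif(p.spacer, window, require_g_in_window),
            bystander_c_count=bystander_c_count(p.spacer, window, p.target_c_pos),
            pam_class=pam_class(p.pam),
        )
        out.append(p)
    return out
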