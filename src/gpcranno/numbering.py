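"""General residue numbering schemes for GPCRs.

GPCR papers refer to residues in up to four ways: plain sequential position,
Ballesteros-Weinstein (BW) generic numbers of the form ``TM.n`` (helix number,
then position relative to the most conserved residue of that helix, e.g.
``3.50``), Oliveira/GPCRDB generic numbers (plain integer labels), or an
article-specific scheme (a sequential scheme shifted by an offset; handled in
:mod:`gpcranno.grounding`). Generic numbers assert structural equivalence of
positions across receptors, independent of sequence numbering.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass


class Scheme(str, enum.Enum):
    SEQUENTIAL = "sequential"
    BALLESTEROS_WEINSTEIN = "ballesteros_weinstein"
    OLIVEIRA = "oliveira"


class BWLabelError(ValueError):
    """Raised for strings that do not denote a Ballesteros-Weinstein number."""


@dataclass(frozen=True)
class GeneralNumber:
    """A scheme-qualified generic residue number.

    For BW numbers ``helix`` is the transmembrane helix (1-8, where 8 covers
    helix 8 / the C-terminal amphipathic helix) and ``index`` the intra-helix
    position; for Oliveira numbers ``helix`` is ``None`` and ``index`` is the
    integer label itself.
    """

    scheme: Scheme
    index: int
    helix: int | None = None

    @property
    def label(self) -> str:
        if self.scheme is Scheme.BALLESTEROS_WEINSTEIN:
            return f"{self.helix}.{self.index:02d}"
        return str(self.index)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_bw_label(label: str) -> GeneralNumber:
    """Parse a Ballesteros-Weinstein ``TM.n`` label such as ``"3.50"``.

    The integer before the period is the transmembrane helix number, the
    two-digit integer after it the position relative to the helix's most
    conserved residue (which is defined as ``.50``).

    Raises :class:`BWLabelError` when the string is not a BW label (wrong
    shape, or helix outside 1-8 -- e.g. ``"9.50"`` is just a decimal number).
    """
    head, sep, tail = label.partition(".")
    if not sep or not head.isdigit() or not (tail.isdigit() and len(tail) == 2):
        raise BWLabelError(f"not a Ballesteros-Weinstein label: {label!r}")
    helix = int(head)
    if not 1 <= helix <= 8:
        raise BWLabelError(f"helix number out of range 1-8: {label!r}")
    return GeneralNumber(
        scheme=Scheme.BALLESTEROS_WEINSTEIN, helix=helix, index=int(tail)
    )


def format_bw(number: GeneralNumber) -> str:
    """Canonical string form of a BW number; inverse of :func:`parse_bw_label`."""
    if number.scheme is not Scheme.BALLESTEROS_WEINSTEIN:
        raise ValueError("not a Ballesteros-Weinstein number")
    return number.label


def oliveira_number(index: int) -> GeneralNumber:
    """Build an Oliveira (GPCRDB) generic number from its integer label."""
    return GeneralNumber(scheme=Scheme.OLIVEIRA, index=int(index))
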