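"""The QA stratification formula mini-language: ``y ~ x | g1 * g2 * ...``.

``y`` is one of the four population statistics (MFI, proportion, count,
spike), ``x`` the plotting/regression variable, and the ``g`` terms the
metadata columns whose observed cross product defines the outlier-detection
groups. An omitted conditioning part means detection over all samples.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import FormulaError

OUTCOMES = ("MFI", "proportion", "count", "spike")


@dataclass(frozen=True)
class Formula:
    outcome: str
    x_var: str
    conditioning: tuple[str, ...] = field(default_factory=tuple)

    def __str__(self) -> str:
        rhs = self.x_var
        if self.conditioning:
            rhs += "|" + "*".join(self.conditioning)
        return f"{self.outcome}~{rhs}"


_TOKEN = r"[A-Za-z_][A-Za-z0-9_.\-]*"
_GRAMMAR = re.compile(
    rf"^\s*({_TOKEN})\s*[~∼]\s*({_TOKEN})\s*(?:\|\s*({_TOKEN}(?:\s*\*\s*{_TOKEN})*)\s*)?$"
)


def parse_formula(text: str) -> Formula:
    """Parse ``y~x|g1*g2`` (both "~" and the tilde operator "∼" accepted)."""
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    m = _GRAMMAR.match(text)
    if m is None:
        raise FormulaError(
            f"formula {text!r} does not match 'y~x|g1*g2*...' "
            f"(y one of {', '.join(OUTCOMES)})"
        )
    outcome, x_var, cond = m.groups()
    if outcome not in OUTCOMES:
        raise FormulaError(
            f"unknown outcome {outcome!r}; legal outcomes: {', '.join(OUTCOMES)}"
        )
    conditioning = tuple(v.strip() for v in cond.split("*")) if cond else ()
    return Formula(outcome=outcome, x_var=x_var, conditioning=conditioning)
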