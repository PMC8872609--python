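"""MICMAC driving/dependence classification.

From the final reachability matrix, each element's driving power is its
row sum (how many elements it reaches, itself included) and its
dependence power the column sum (how many elements reach it). A midpoint
— by default n/2 — splits each axis into low/high, giving the four
classical quadrants:

* **autonomous** — low driving, low dependence: detached elements;
* **dependent** — low driving, high dependence: outcome tier;
* **linkage** — high driving, high dependence: unstable amplifiers;
* **independent** — high driving, low dependence: root drivers.

"High" means strictly greater than the midpoint. When the power
distribution is bimodal the quadrants are invariant to any midpoint in
the gap between the clusters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TextIO

import pandas as pd

from .errors import NotClosedWarning, ValidationError
from .ism import ReachabilityMatrix, transitive_closure
from .register import code_sort_key

QUADRANTS = ("autonomous", "dependent", "linkage", "independent")


@dataclass(frozen=True)
class MicmacPowers:
    """Per-element driving (row-sum) and dependence (column-sum) powers."""

    elements: tuple[str, ...]
    driving: dict[str, int]
    dependence: dict[str, int]

    @property
    def n(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class MicmacResult:
    """Powers plus quadrant labels under a given midpoint."""

    powers: MicmacPowers
    midpoint: float
    quadrant: dict[str, str]

    @property
    def elements(self) -> tuple[str, ...]:
        return self.powers.elements

    def members(self, quadrant: str) -> tuple[str, ...]:
        if quadrant not in QUADRANTS:
            raise ValidationError(f"unknown quadrant {quadrant!r}")
        return tuple(
            sorted((c for c, q in self.quadrant.items() if q == quadrant), key=code_sort_key)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": list(self.elements),
                "driving_power": [self.powers.driving[c] for c in self.elements],
                "dependence_power": [self.powers.dependence[c] for c in self.elements],
                "quadrant": [self.quadrant[c] for c in self.elements],
            }
        )

    def to_csv(self, dest: str | Path | TextIO) -> None:
        df = self.to_frame()
        if isinstance(dest, (str, Path)):
            df.to_csv(dest, index=False)
        else:
            dest.write(df.to_csv(index=False))

    def summary_json(self) -> str:
        return json.dumps(
            {
                "midpoint": self.midpoint,
                "quadrants": {q: list(self.members(q)) for q in QUADRANTS},
            },
            indent=2,
        )


def powers(final: ReachabilityMatrix) -> MicmacPowers:
    """Row/column 1-counts of the final matrix.

    If the input is not actually closed, a warning is raised and the
    closure is used, so the powers always describe a final matrix.
    """
    if not final.is_closed():
        warnings.warn(
            "matrix is not transitively closed; computing powers on its closure",
            NotClosedWarning,
            stacklevel=2,
        )
        final = transitive_closure(final)
    row = final.values.sum(axis=1)
    col = final.values.sum(axis=0)
    return MicmacPowers(
        final.elements,
        {c: int(row[i]) for i, c in enumerate(final.elements)},
        {c: int(col[i]) for i, c in enumerate(final.elements)},
    )


def classify(p: MicmacPowers, midpoint: float | str = "auto") -> MicmacResult:
    """Assign each element to a quadrant; ``auto`` midpoint = n/2."""
    mid = p.n / 2 if midpoint == "auto" else float(midpoint)
    if not (0 < mid < p.n):
        raise ValidationError(f"midpoint must lie strictly between 0 and {p.n}")
    quad: dict[str, str] = {}
    for c in p.elements:
        hi_drv = p.driving[c] > mid
        hi_dep = p.dependence[c] > mid
        quad[c] = (
            "linkage" if hi_drv and hi_dep
            else "independent" if hi_drv
            else "dependent" if hi_dep
            else "autonomous"
        )
    return MicmacResult(p, mid, quad)


def micmac(final: ReachabilityMatrix, midpoint: float | str = "auto") -> MicmacResult:
    """Convenience: powers + classification in one call."""
    return classify(powers(final), midpoint)
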