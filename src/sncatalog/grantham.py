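"""Grantham physicochemical distances between amino acids.

The Grantham distance combines side-chain composition (c), polarity (p) and
molecular volume (v) into

    D(i, j) = rho * sqrt(alpha*(c_i - c_j)^2 + beta*(p_i - p_j)^2
                         + gamma*(v_i - v_j)^2)

rounded to the nearest integer, with the constants published alongside the
original 1974 matrix.  Missense changes are scored from the bundled published
matrix (``grantham_score``), the scores used throughout the literature; the
analytic formula is exposed as :class:`GranthamParams` for parameter studies.
The published table was produced with 1974-era arithmetic and differs from a
fresh evaluation of the formula by one unit for a minority of pairs (and by
ten for D-W); both routes are available and the discrepancy is documented in
the methods note.

Scores above 180 mark radical ("deleterious") substitutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping

import pandas as pd

#: amino acids in the original table order
AMINO_ACIDS = tuple("SRLPTAVGIFYCHQNKDEMW")

#: side-chain composition, polarity, volume (published property values)
PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0), "R": (0.65, 10.5, 124.0), "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5), "T": (0.71, 8.6, 61.0), "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0), "G": (0.74, 9.0, 3.0), "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0), "Y": (0.20, 6.2, 136.0), "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0), "Q": (0.89, 10.5, 85.0), "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0), "D": (1.38, 13.0, 54.0), "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0), "W": (0.13, 5.4, 170.0),
}

#: deleteriousness cutoff: scores strictly above this are radical changes
DELETERIOUS_CUTOFF = 180


@dataclass(frozen=True)
class GranthamParams:
    """Constants of the Grantham distance formula."""

    alpha: float = 1.833
    beta: float = 0.1018
    gamma: float = 0.000399
    rho: float = 50.723
    properties: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(PROPERTIES))

    def distance(self, a: str, b: str) -> int:
        """Formula evaluation, rounded half-up to the nearest integer."""
        if a not in self.properties or b not in self.properties:
            raise ValueError(f"not a standard amino acid: {a!r}/{b!r}")
        c1, p1, v1 = self.properties[a]
        c2, p2, v2 = self.properties[b]
        raw = math.sqrt(self.alpha * (c1 - c2) ** 2
                        + self.beta * (p1 - p2) ** 2
                        + self.gamma * (v1 - v2) ** 2)
        return math.floor(self.rho * raw + 0.5)

    def matrix(self) -> pd.DataFrame:
        """Full 20x20 distance matrix computed from the formula."""
        aas = list(AMINO_ACIDS)
        return pd.DataFrame(
            [[self.distance(a, b) for b in aas] for a in aas],
            index=aas, columns=aas)


@lru_cache(maxsize=1)
def published_matrix() -> pd.DataFrame:
    """The bundled published 20x20 Grantham matrix (integer, symmetric)."""
    with resources.files("sncatalog.data").joinpath(
            "grantham_published.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df.astype(int)


def grantham_score(ref_aa: str, alt_aa: str) -> int:
    """Published Grantham score for an amino-acid substitution (0 if equal)."""
    m = published_matrix()
    if ref_aa not in m.index or alt_aa not in m.index:
        raise ValueError(f"not a standard amino acid: {ref_aa!r}/{alt_aa!r}")
    return int(m.loc[ref_aa, alt_aa])


def is_radical(score: int) -> bool:
    """True for scores strictly above the 180 cutoff."""
    return score > DELETERIOUS_CUTOFF
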