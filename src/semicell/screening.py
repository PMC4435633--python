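"""Three-zone screening of distant electrostatic interactions.

Distant charges are relocated to an effective distance ``r_eff`` and the
distributed multipoles that represent orbital-pair charge distributions are
contracted toward point charges by a factor ``λ``:

* ``r < α``       : nothing changes (``r_eff = r``, ``λ = 1``);
* ``α ≤ r ≤ 2α``  : ``r_eff = -α/2 + 2r - r²/(2α)``, ``λ = 2 - r/α``
                    (``λ`` is d(r_eff)/dr, so charge images move smoothly);
* ``r > 2α``      : all centers sit at the constant radius ``1.5α`` and every
                    multipole of order ≥ 1 has collapsed to coincident point
                    charges, so the contributions of distant *neutral* cells
                    cancel by symmetry and the lattice sum terminates.

``α`` is configured through the ``ScreeningR`` keyword, whose value is ``2α``
in Å (default 30.0 Å).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_SCREENING_R = 30.0  # Å, = 2α


@dataclass(frozen=True)
class ScreeningSpec:
    """Screening radius bookkeeping; ``alpha`` in Å."""

    alpha: float = DEFAULT_SCREENING_R / 2.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("screening radius must be positive")

    @classmethod
    def from_screening_r(cls, screening_r: float) -> "ScreeningSpec":
        """Build from the ``ScreeningR`` keyword value (= 2α, Å)."""
        return cls(alpha=screening_r / 2.0)

    @property
    def two_alpha(self) -> float:
        return 2.0 * self.alpha


def effective_distance(r, alpha: float):
    """Effective interaction distance r_eff(r); continuous, plateaus at 1.5α."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    mid = -alpha / 2.0 + 2.0 * r - r * r / (2.0 * alpha)
    out = np.where(r < alpha, r, np.where(r <= 2.0 * alpha, mid, 1.5 * alpha))
    return float(out) if out.ndim == 0 else out


def multipole_contraction(r, alpha: float):
    """Multipole contraction factor λ(r) = d(r_eff)/dr on the middle zone."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    out = np.where(r < alpha, 1.0,
                   np.where(r <= 2.0 * alpha, 2.0 - r / alpha, 0.0))
    return float(out) if out.ndim == 0 else out


def screen_pair(set_a, set_b, r: float, alpha: float):
    """Screen a pair of multipole charge sets at center separation ``r``.

    Returns ``(r_eff, set_a', set_b')`` where the primed sets have every
    point-charge offset multiplied by λ(r); charge magnitudes are unchanged,
    so the total charge of each set is conserved exactly.  Beyond ``2α`` all
    offsets vanish: neutral multipoles then contribute nothing.
    """
    lam = multipole_contraction(r, alpha)
    return (effective_distance(r, alpha),
            set_a.scaled_offsets(lam), set_b.scaled_offsets(lam))
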