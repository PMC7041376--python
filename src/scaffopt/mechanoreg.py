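"""Prendergast-Huiskes mechanoregulation of tissue differentiation.

Mesenchymal stem cells invading the scaffold pores differentiate according to
the biophysical stimulus

    S = gamma / a + v / b

where ``gamma`` is the octahedral shear strain of the granulation tissue,
``v`` the interstitial (Darcy) fluid speed, and ``a = 0.0375`` (3.75 %),
``b = 3 um/s`` are empirical constants.  Stimulus bands map to phenotypes:

    S in [0, 0.01)    -> bone resorption
    S in [0.01, 0.53) -> mature bone
    S in [0.53, 1)    -> immature bone
    S in [1, 3)       -> cartilage
    S in [3, inf)     -> fibrous tissue

The published bands are open intervals (measure-zero gaps at the
breakpoints); here bins are half-open, closed on the lower edge, so that
every S >= 0 receives exactly one phenotype.

The design score of a scaffold is BO% = 100 * V_BONE / V_TOT: the share of
the total modeled volume predicted to mineralize into mature bone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import ElementStates
from .geometry import GRANULATION

__all__ = [
    "MechanoregParams",
    "PHENOTYPES",
    "StimulusSummary",
    "octahedral_shear_strain",
    "stimulus",
    "classify",
    "bone_fraction",
]

PHENOTYPES = ("resorption", "mature_bone", "immature_bone", "cartilage", "fibrous")


@dataclass(frozen=True)
class MechanoregParams:
    """Stimulus constants and phenotype breakpoints.

    ``a`` is dimensionless (strain as a fraction: 0.0375 == 3.75 %); ``b``
    is in um/s.  ``thresholds`` are the lower edges of the five phenotype
    bins above 0.
    """

    a: float = 0.0375
    b_um_s: float = 3.0
    thresholds: tuple[float, ...] = (0.01, 0.53, 1.0, 3.0)

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b_um_s <= 0:
            raise ValueError("constants a and b must be positive")
        t = np.asarray(self.thresholds)
        if t.size != 4 or np.any(np.diff(t) <= 0) or t[0] <= 0:
            raise ValueError("thresholds must be 4 strictly increasing positives")


@dataclass
class StimulusSummary:
    """Per-element stimulus/phenotype fields plus the bone-volume score."""

    S: np.ndarray
    phenotype: np.ndarray            # indices into PHENOTYPES
    V_BONE_mm3: float
    V_TOT_mm3: float
    bin_volumes_mm3: dict[str, float] = field(default_factory=dict)

    @property
    def BO_percent(self) -> float:
        return 100.0 * self.V_BONE_mm3 / self.V_TOT_mm3

    def bin_counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.phenotype == i))
            for i, name in enumerate(PHENOTYPES)
        }


def octahedral_shear_strain(eps_I, eps_II, eps_III):
    """Octahedral shear strain from principal strains (any broadcastable shape).

    gamma = (2/3) sqrt((e_I - e_II)^2 + (e_II - e_III)^2 + (e_I - e_III)^2);
    zero for hydrostatic states, symmetric in its arguments, insensitive to a
    uniform shift of all three strains.
    """
    e1, e2, e3 = np.asarray(eps_I), np.asarray(eps_II), np.asarray(eps_III)
    if not (np.all(np.isfinite(e1)) and np.all(np.isfinite(e2))
            and np.all(np.isfinite(e3))):
        raise ValueError("principal strains must be finite")
    g = (2.0 / 3.0) * np.sqrt(
        (e1 - e2) ** 2 + (e2 - e3) ** 2 + (e1 - e3) ** 2
    )
    return g if g.ndim else float(g)


def stimulus(gamma, v_um_s, params: MechanoregParams = MechanoregParams()):
    """Biophysical stimulus S = gamma/a + v/b (both terms dimensionless)."""
    g = np.asarray(gamma, dtype=float)
    v = np.asarray(v_um_s, dtype=float)
    if np.any(g < 0) or np.any(v < 0):
        raise ValueError("gamma and v must be non-negative")
    S = g / params.a + v / params.b_um_s
    return S if S.ndim else float(S)


def classify(S, params: MechanoregParams = MechanoregParams()):
    """Map stimulus values to phenotype bin indices (see PHENOTYPES).

    Bins are half-open, closed below: e.g. S = 0.53 is immature bone.
    """
    Sa = np.asarray(S, dtype=float)
    if np.any(Sa < 0):
        raise ValueError("stimulus must be non-negative")
    idx = np.searchsorted(np.asarray(params.thresholds), Sa, side="right")
    return idx if idx.ndim else int(idx)


def phenotype_name(index: int) -> str:
    return PHENOTYPES[index]


def bone_fraction(
    states: ElementStates,
    params: MechanoregParams = MechanoregParams(),
    V_TOT_mm3: float | None = None,
) -> StimulusSummary:
    """Score a solved model: stimulus, phenotypes, and BO% over V_TOT.

    Only granulation-phase elements differentiate; scaffold elements are
    excluded from the stimulus bookkeeping (pass the full state list, the
    restriction happens here).  ``V_TOT_mm3`` defaults to the summed volume
    of all elements, both phases.
    """
    if V_TOT_mm3 is None:
        V_TOT_mm3 = float(np.sum(states.volume_mm3))
    gran = states.granulation_only() if np.any(states.phase != GRANULATION) else states
    if len(gran) == 0:
        import warnings

        warnings.warn("no granulation elements: BO% = 0", stacklevel=2)
        return StimulusSummary(
            S=np.empty(0), phenotype=np.empty(0, dtype=int),
            V_BONE_mm3=0.0, V_TOT_mm3=V_TOT_mm3,
        )
    gamma = octahedral_shear_strain(gran.eps_I, gran.eps_II, gran.eps_III)
    S = stimulus(gamma, gran.v_um_s, params)
    phen = classify(S, params)
    mature = phen == PHENOTYPES.index("mature_bone")
    V_BONE = float(np.sum(gran.volume_mm3[mature]))
    bins = {
        name: float(np.sum(gran.volume_mm3[phen == i]))
        for i, name in enumerate(PHENOTYPES)
    }
    return StimulusSummary(
        S=S, phenotype=phen, V_BONE_mm3=V_BONE, V_TOT_mm3=V_TOT_mm3,
        bin_volumes_mm3=bins,
    )
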