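"""Flip-mechanism efficacy algebra for ligand-gated ion channels.

At saturating agonist a channel shuttles between an agonist-bound resting
(shut) state, a pre-open intermediate ("flipped", shut but higher-affinity)
and the open state.  Two equilibrium constants govern gating:

* ``F`` — flipping equilibrium constant (flipped / resting occupancy),
* ``E`` — opening equilibrium constant (open / flipped occupancy).

The maximum open probability within a cluster of activity is

    max P_open = E·F / (E·F + F + 1)

which collapses to the del Castillo–Katz form

    max P_open = Eff / (Eff + 1),      Eff = E·F / (F + 1)

where ``Eff`` is the overall gating constant of the agonist.  Because a
measured maximum P_open determines Eff uniquely, single-channel cluster data
let one rank agonist efficacies and predict how P_open shifts when gating is
enhanced (e.g. when a construct change multiplies E by a common factor).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FlipMechanism",
    "EfficacyEstimate",
    "eff_from_EF",
    "popen_from_EF",
    "popen_from_eff",
    "eff_from_popen",
    "predict_popen_scaled_E",
    "percent_change",
]


def _require_positive(value: float, name: str) -> float:
    value = float(value)
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")
    return value


@dataclass(frozen=True)
class FlipMechanism:
    """Equilibrium description of gating at saturating agonist.

    Parameters
    ----------
    E : float
        Opening equilibrium constant (open/flipped), dimensionless, > 0.
    F : float
        Flipping equilibrium constant (flipped/resting), dimensionless, > 0.
    """

    E: float
    F: float

    def __post_init__(self) -> None:
        _require_positive(self.E, "E")
        _require_positive(self.F, "F")

    @property
    def eff(self) -> float:
        """Overall gating constant Eff = E·F/(F+1)."""
        return eff_from_EF(self.E, self.F)

    @property
    def popen_max(self) -> float:
        """Maximum open probability E·F/(E·F+F+1)."""
        return popen_from_EF(self.E, self.F)

    def scaled_E(self, factor: float) -> "FlipMechanism":
        """Mechanism with the opening constant multiplied by ``factor``."""
        _require_positive(factor, "factor")
        return FlipMechanism(self.E * factor, self.F)


@dataclass(frozen=True)
class EfficacyEstimate:
    """An (Eff, max P_open) pair and where it came from.

    ``source`` is ``"from_EF"`` when computed from a full mechanism and
    ``"from_popen"`` when obtained by inverting a measured open probability.
    """

    popen_max: float
    eff: float
    source: str

    def __post_init__(self) -> None:
        if abs(self.popen_max - self.eff / (self.eff + 1.0)) > 1e-12:
            raise ValueError("popen_max and eff are inconsistent")

    @classmethod
    def from_EF(cls, E: float, F: float) -> "EfficacyEstimate":
        eff = eff_from_EF(E, F)
        return cls(popen_max=popen_from_eff(eff), eff=eff, source="from_EF")

    @classmethod
    def from_popen(cls, popen: float) -> "EfficacyEstimate":
        eff = eff_from_popen(popen)
        # re-map through Eff so the pair is consistent to machine precision
        return cls(popen_max=popen_from_eff(eff), eff=eff, source="from_popen")


def eff_from_EF(E: float, F: float) -> float:
    """Overall gating constant Eff = E·F/(F+1).

    >>> round(eff_from_EF(38, 8), 2)
    33.78
    """
    E = _require_positive(E, "E")
    F = _require_positive(F, "F")
    return E * F / (F + 1.0)


def popen_from_EF(E: float, F: float) -> float:
    """Maximum open probability E·F/(E·F+F+1).

    >>> round(popen_from_EF(38, 8), 4)
    0.9712
    """
    E = _require_positive(E, "E")
    F = _require_positive(F, "F")
    ef = E * F
    return ef / (ef + F + 1.0)


def popen_from_eff(eff: float) -> float:
    """Map the overall gating constant to maximum open probability.

    Strictly increasing, with values in (0, 1); Eff = 1 gives 0.5.
    """
    eff = _require_positive(eff, "Eff")
    return eff / (eff + 1.0)


def eff_from_popen(popen: float) -> float:
    """Invert ``popen_from_eff``: Eff = p/(1-p) for p in (0, 1).

    Boundary open probabilities (0 or 1, possible for very short clusters)
    are rejected rather than clamped — the inversion is undefined there and
    clamping would bias group means.
    """
    popen = float(popen)
    if not 0.0 < popen < 1.0:
        raise ValueError(
            f"popen must lie strictly in (0, 1) to be invertible, got {popen!r}"
        )
    return popen / (1.0 - popen)


def predict_popen_scaled_E(popen0: float, factor: float) -> float:
    """Predicted maximum P_open after scaling the opening constant E.

    With F fixed, multiplying E by ``factor`` multiplies Eff = E·F/(F+1) by
    exactly the same factor, so the prediction needs only the starting
    open probability:  p -> popen_from_eff(factor · p/(1-p)).
    """
    _require_positive(factor, "factor")
    return popen_from_eff(factor * eff_from_popen(popen0))


def percent_change(before: float, after: float) -> float:
    """Signed percent change 100·(after-before)/before.

    Used to express efficacy shifts between constructs, e.g. a P_open change
    from 0.09 to 0.70 is +677.8%.
    """
    before = float(before)
    after = float(after)
    if not 0.0 < before <= 1.0:
        raise ValueError(f"before must lie in (0, 1], got {before!r}")
    if not 0.0 <= after <= 1.0:
        raise ValueError(f"after must lie in [0, 1], got {after!r}")
    return 100.0 * (after - before) / before
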