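"""Mechanical parameters of the dimensionless vertex model.

Every cell carries the energy

    U = (A - 1)^2 + (Gamma/2) * (L + Lambda / (2 Gamma))^2

where ``A`` and ``L`` are the dimensionless apical area and perimeter,
``Gamma`` is the cortical contractility/stiffness coefficient and
``Lambda`` is a line-tension-like parameter prescribing the preferred
perimeter ``L0 = -Lambda / (2 Gamma)``.  The default values
``(Lambda, Gamma) = (0.259, 0.172)`` were previously fitted to the
Xenopus laevis animal-cap epithelium.

Hyper-contractile (kRas^V12-like) cluster cells are modelled by scaling
``Gamma`` by ``1 + cluster_increment`` in those cells only.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MechanicalParams:
    """Dimensionless vertex-model coefficients.

    Parameters
    ----------
    lambda_coeff:
        Line-tension-like parameter (Lambda). Together with ``gamma_ref``
        it sets the preferred perimeter ``L0 = -Lambda / (2 Gamma)``.
    gamma_ref:
        Reference cortical contractility/stiffness (Gamma); must be > 0.
    cluster_increment:
        Fractional increase of Gamma inside the flagged cluster
        (0.09 means a 9% increase); must be >= 0.
    """

    lambda_coeff: float = 0.259
    gamma_ref: float = 0.172
    cluster_increment: float = 0.0

    def __post_init__(self) -> None:
        if not self.gamma_ref > 0:
            raise ValueError(f"gamma_ref must be positive, got {self.gamma_ref}")
        if self.cluster_increment < 0:
            raise ValueError(
                f"cluster_increment must be >= 0, got {self.cluster_increment}"
            )

    @property
    def preferred_perimeter(self) -> float:
        """Preferred perimeter L0 = -Lambda / (2 Gamma)."""
        return -self.lambda_coeff / (2.0 * self.gamma_ref)

    def with_increment(self, cluster_increment: float) -> "MechanicalParams":
        """Copy of the parameters with a different cluster increment."""
        return MechanicalParams(
            lambda_coeff=self.lambda_coeff,
            gamma_ref=self.gamma_ref,
            cluster_increment=cluster_increment,
        )
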