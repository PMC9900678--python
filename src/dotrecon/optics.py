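"""Tissue optical properties for the diffusion approximation."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering of one tissue region.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1.
    mu_s_prime : float
        Reduced scattering coefficient, mm^-1.

    The diffusion coefficient is ``D = 1 / (3 (mu_a + mu_s_prime))`` (mm),
    the form used by the frequency-domain diffusion operator.
    """

    mu_a: float
    mu_s_prime: float

    def __post_init__(self) -> None:
        if not (self.mu_a > 0):
            raise ValueError(f"mu_a must be > 0, got {self.mu_a}")
        if not (self.mu_s_prime > 0):
            raise ValueError(f"mu_s_prime must be > 0, got {self.mu_s_prime}")

    @property
    def diffusion(self) -> float:
        """Diffusion coefficient D = 1/(3(mu_a + mu_s_prime)), mm."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    def scaled(self, contrast_a: float, contrast_s: float) -> "OpticalProperties":
        """Return properties multiplied by per-coefficient contrast factors."""
        return OpticalProperties(self.mu_a * contrast_a, self.mu_s_prime * contrast_s)
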