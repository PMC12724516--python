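"""Four-parameter log-logistic dose-response fitting and ICx estimation.

Viability v(d) = lower + (upper - lower) / (1 + (d / ec50)^hill), fitted by
least squares to responses normalized to the untreated mean.  ICx, the
concentration inhibiting the readout by x% relative to control, follows in
closed form: ICx = ec50 * (x / (100 - x))^(1 / hill).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


def four_param_logistic(dose, lower, upper, hill, ec50):
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, dose / ec50, 0.0)
    return lower + (upper - lower) / (1.0 + ratio**hill)


@dataclass
class DoseResponseResults:
    """Fitted 4PL parameters, residuals and ICx inversion."""

    lower: float
    upper: float
    hill: float
    ec50: float
    doses: np.ndarray
    responses: np.ndarray
    residuals: np.ndarray
    converged: bool
    flags: list[str] = field(default_factory=list)

    def icx(self, x: float) -> float:
        """Concentration at x% inhibition of the (upper - lower) span."""
        if not (0 < x < 100):
            raise ValueError("x must be in (0, 100)")
        if not self.converged or "no_inhibition" in self.flags:
            return float("nan")
        return float(self.ec50 * (x / (100.0 - x)) ** (1.0 / self.hill))

    @property
    def ic25(self) -> float:
        return self.icx(25.0)

    @property
    def ic50(self) -> float:
        return self.icx(50.0)

    def predict(self, doses):
        return four_param_logistic(doses, self.lower, self.upper, self.hill, self.ec50)

    def summary(self) -> str:
        lines = [
            "Four-parameter log-logistic dose-response fit",
            "=" * 46,
            f"n observations     {len(self.doses):>10d}",
            f"lower asymptote    {self.lower:>10.4f}",
            f"upper asymptote    {self.upper:>10.4f}",
            f"hill slope         {self.hill:>10.4f}",
            f"EC50               {self.ec50:>10.4f}",
            f"IC25               {self.ic25:>10.4f}",
            f"IC50               {self.ic50:>10.4f}",
            f"residual SS        {float(np.sum(self.residuals ** 2)):>10.3e}",
        ]
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


class DoseResponseModel:
    """4PL viability model for one exposure series.

    Parameters
    ----------
    doses : concentrations (same units as the reported ICx; must include 0
        and at least 4 distinct levels).
    responses : viability readouts; normalized internally to the mean
        response at dose 0 unless ``normalized=True``.
    """

    def __init__(self, doses, responses, normalized: bool = False):
        doses = np.asarray(doses, dtype=float)
        responses = np.asarray(responses, dtype=float)
        if doses.shape != responses.shape:
            raise ValueError("doses and responses must have the same shape")
        if len(np.unique(doses)) < 4:
            raise ValueError("need at least 4 distinct dose levels")
        if not (doses == 0).any():
            raise ValueError("doses must include an untreated (0) level")
        if not normalized:
            responses = responses / responses[doses == 0].mean()
        order = np.argsort(doses)
        self.doses = doses[order]
        self.responses = responses[order]

    def fit(self) -> DoseResponseResults:
        d, r = self.doses, self.responses
        flags: list[str] = []
        span = r.max() - r.min()
        if span < 0.05:  # effectively flat: no inhibition to invert
            flags.append("no_inhibition")
            return DoseResponseResults(
                lower=float(r.mean()), upper=float(r.mean()), hill=1.0,
                ec50=float("nan"), doses=d, responses=r,
                residuals=r - r.mean(), converged=False, flags=flags,
            )
        pos = d[d > 0]
        p0 = [max(r.min(), 0.0), r[d == 0].mean(), 1.0, float(np.median(pos))]
        bounds = ([-0.5, 0.0, 0.05, pos.min() / 100], [1.0, 2.0, 20.0, pos.max() * 100])
        try:
            popt, _ = curve_fit(
                four_param_logistic, d, r, p0=p0, bounds=bounds, maxfev=20000
            )
            converged = True
        except RuntimeError:
            popt, converged = p0, False
            flags.append("fit_failed")
        lower, upper, hill, ec50 = (float(v) for v in popt)
        if converged and upper - lower < 0.05:
            flags.append("no_inhibition")
        residuals = r - four_param_logistic(d, *popt)
        return DoseResponseResults(
            lower=lower, upper=upper, hill=hill, ec50=ec50,
            doses=d, responses=r, residuals=residuals,
            converged=converged, flags=flags,
        )


def estimate_icx(doses, responses, x: float = 25.0) -> DoseResponseResults:
    """Convenience wrapper: fit the 4PL; the result carries ``icx(x)``."""
    return DoseResponseModel(doses, responses).fit()
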