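"""Titration-curve fitting for constant-pH simulation output.

The protonated fraction of a titratable base follows the Hill-generalised
Henderson–Hasselbalch curve

    f_prot(pH) = 1 / (1 + 10^{n·(pH − pKa)}) ,

which decreases with pH and crosses 1/2 at pH = pKa.  A least-squares fit
(binomially weighted when per-pH sample counts are known) returns pKa and
the Hill coefficient n with curvature-based standard errors; a classifier
maps the model fraction at a working pH to protonated / neutral / mixed.
An acid-form convention (fraction rising with pH) is available via a flag.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["TitrationSeries", "TitrationFit", "hill_fraction", "fit_titration", "classify_at_ph"]


def hill_fraction(ph, pka: float, hill: float = 1.0, acid_form: bool = False):
    """Model protonated fraction at pH for a base (default) or an acid."""
    x = np.asarray(ph, dtype=float)
    sign = -1.0 if acid_form else 1.0
    return 1.0 / (1.0 + 10.0 ** (sign * hill * (x - pka)))


@dataclass
class TitrationSeries:
    """Protonated fraction vs pH for one residue.

    ``counts`` (samples per pH) enables binomial weighting; pass it when
    the fractions derive from 0/1 protonation records.
    """

    residue: str
    ph: np.ndarray
    fraction: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.ph.shape != self.fraction.shape:
            raise ValueError("ph and fraction must align")
        if np.any(np.diff(self.ph) <= 0):
            raise ValueError("pH grid must be strictly increasing")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != self.ph.shape or np.any(self.counts < 1):
                raise ValueError("counts must align with ph and be ≥ 1")

    @classmethod
    def from_samples(cls, residue: str, ph, samples_by_ph) -> "TitrationSeries":
        """Build from raw 0/1 protonation samples, one array per pH."""
        frac = np.array([np.mean(s) for s in samples_by_ph], dtype=float)
        counts = np.array([len(s) for s in samples_by_ph], dtype=float)
        return cls(residue, np.asarray(ph, dtype=float), frac, counts)


@dataclass
class TitrationFit:
    pka: float
    hill: float
    pka_stderr: float
    hill_stderr: float
    residual_norm: float
    acid_form: bool = False

    def fraction_at(self, ph) -> float | np.ndarray:
        return hill_fraction(ph, self.pka, self.hill, self.acid_form)


def fit_titration(
    series: TitrationSeries,
    acid_form: bool = False,
    fix_hill: bool = False,
) -> TitrationFit:
    """Least-squares Hill/Henderson–Hasselbalch fit of a titration series.

    Requires ≥ 4 pH points and non-degenerate fractions (not all at one
    extreme).  With sample counts present, residuals are weighted by the
    binomial standard deviation (variance-floored so exact 0/1 fractions
    keep finite weight).  ``fix_hill`` constrains the Hill coefficient to 1.
    """
    if series.ph.size < 4:
        raise ValueError("titration fit needs at least 4 pH points")
    f = series.fraction
    if np.all(f <= 0.0) or np.all(f >= 1.0):
        raise ValueError("titration is non-identifiable: all fractions at one extreme")

    pka0 = float(series.ph[np.argmin(np.abs(f - 0.5))])
    sigma = None
    if series.counts is not None:
        var = np.maximum(f * (1 - f), 1e-4) / series.counts
        sigma = np.sqrt(var)

    if fix_hill:
        def model(ph, pka):
            return hill_fraction(ph, pka, 1.0, acid_form)
        p0, names = [pka0], ["pka"]
    else:
        def model(ph, pka, hill):
            return hill_fraction(ph, pka, hill, acid_form)
        p0, names = [pka0, 1.0], ["pka", "hill"]

    popt, pcov = curve_fit(
        model, series.ph, f, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
        maxfev=10000,
    )
    perr = np.sqrt(np.diag(pcov))
    resid = f - model(series.ph, *popt)
    pka = float(popt[0])
    hill = 1.0 if fix_hill else float(popt[1])
    if hill <= 0:
        raise ValueError("fitted Hill coefficient is non-positive")
    return TitrationFit(
        pka=pka,
        hill=hill,
        pka_stderr=float(perr[0]),
        hill_stderr=0.0 if fix_hill else float(perr[1]),
        residual_norm=float(np.linalg.norm(resid)),
        acid_form=acid_form,
    )


def classify_at_ph(
    fit: TitrationFit,
    ph: float,
    protonated_above: float = 0.9,
    neutral_below: float = 0.1,
) -> tuple[str, float]:
    """Protonation-state call at a working pH from the fitted curve.

    Returns ``("protonated"|"neutral"|"mixed", model fraction)`` using the
    configurable thresholds (defaults 0.9 / 0.1).
    """
    frac = float(fit.fraction_at(ph))
    if frac > protonated_above:
        state = "protonated"
    elif frac < neutral_below:
        state = "neutral"
    else:
        state = "mixed"
    return state, frac
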