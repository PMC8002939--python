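"""DNA-content (propidium-iodide-style) histogram simulation and fitting.

A fixed, stained cell population produces a one-dimensional DNA-content
distribution: a 2N peak (G1/G0 cells), a 4N peak at exactly twice its
location (G2/M cells), and a plateau of S-phase cells replicating between
the two.  The generative model used both for simulation and for fitting
is the classic one:

* G1/G0 events ~ Normal(mu, cv*mu),
* G2/M events ~ Normal(2*mu, cv*2*mu)  (ploidy doubling, shared cv),
* S events ~ Uniform(mu, 2*mu) convolved with Normal(0, cv*mu),

whose mixture weights are the cycle fractions.  Fitting is a
least-squares match of this shape to a binned histogram, statsmodels
style: construct a :class:`DnaMixtureModel` from the histogram, call
:meth:`~DnaMixtureModel.fit`, read fractions and diagnostics off the
returned :class:`DnaMixtureResults`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, stats

DEFAULT_MU = 100.0
MIN_EVENTS_FOR_FIT = 1000


@dataclasses.dataclass(frozen=True)
class CycleFractions:
    """G1/G0, S and G2/M fractions of a cycling population."""

    g1_g0: float
    s: float
    g2m: float

    def __post_init__(self) -> None:
        for name, v in dataclasses.asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} fraction {v} outside [0, 1]")
        total = self.g1_g0 + self.s + self.g2m
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions sum to {total}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.g1_g0, self.s, self.g2m])


@dataclasses.dataclass(frozen=True)
class DnaHistogram:
    """Binned DNA-content events (arbitrary fluorescence units)."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if edges.ndim != 1 or counts.ndim != 1 or edges.size != counts.size + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def n_events(self) -> int:
        return int(round(float(self.counts.sum())))

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_events(cls, events, bin_edges=None, mu: float = DEFAULT_MU) -> "DnaHistogram":
        events = np.asarray(events, dtype=float)
        if bin_edges is None:
            bin_edges = np.linspace(0.0, 3.0 * mu, 241)
        counts, edges = np.histogram(events, bins=bin_edges)
        return cls(bin_edges=edges, counts=counts.astype(float))


def simulate_dna_events(
    fractions: CycleFractions, n_events: int, cv: float, seed, mu: float = DEFAULT_MU
) -> np.ndarray:
    """Draw raw per-event DNA-content values from the generative model."""
    if not 0.0 < cv <= 0.15:
        raise ValueError("cv must be in (0, 0.15]")
    rng = np.random.default_rng(seed)
    phase = rng.choice(3, size=n_events, p=fractions.as_array())
    values = np.empty(n_events)
    n_g1 = int(np.sum(phase == 0))
    n_s = int(np.sum(phase == 1))
    n_g2m = int(np.sum(phase == 2))
    values[phase == 0] = rng.normal(mu, cv * mu, n_g1)
    values[phase == 1] = rng.uniform(mu, 2 * mu, n_s) + rng.normal(0, cv * mu, n_s)
    values[phase == 2] = rng.normal(2 * mu, cv * 2 * mu, n_g2m)
    return values


def simulate_dna_content(
    fractions: CycleFractions,
    n_events: int,
    cv: float,
    seed,
    mu: float = DEFAULT_MU,
    bin_edges=None,
) -> DnaHistogram:
    """Simulate a binned DNA-content histogram (see module docstring)."""
    events = simulate_dna_events(fractions, n_events, cv, seed, mu=mu)
    return DnaHistogram.from_events(events, bin_edges=bin_edges, mu=mu)


def _phase_bin_probs(bin_edges: np.ndarray, mu: float, cv: float) -> np.ndarray:
    """Per-bin probability mass of each phase: rows (G1, S, G2M)."""
    sd1 = cv * mu
    g1 = np.diff(stats.norm.cdf(bin_edges, mu, sd1))
    g2m = np.diff(stats.norm.cdf(bin_edges, 2 * mu, 2 * sd1))
    # S: Uniform(mu, 2mu) + Normal(0, sd1); CDF has the closed form below.
    def s_cdf(x):
        a, b = mu, 2 * mu
        za = (x - a) / sd1
        zb = (x - b) / sd1
        return (
            (x - a) * stats.norm.cdf(za)
            - (x - b) * stats.norm.cdf(zb)
            + sd1 * (stats.norm.pdf(za) - stats.norm.pdf(zb))
        ) / (b - a)

    s = np.diff(s_cdf(bin_edges))
    return np.vstack([g1, s, g2m])


def expected_histogram(
    fractions: CycleFractions,
    n_events: int,
    cv: float,
    mu: float = DEFAULT_MU,
    bin_edges=None,
) -> DnaHistogram:
    """Noise-free (analytic) expected histogram of the generative model."""
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 3.0 * mu, 241)
    bin_edges = np.asarray(bin_edges, dtype=float)
    probs = _phase_bin_probs(bin_edges, mu, cv)
    counts = n_events * fractions.as_array() @ probs
    return DnaHistogram(bin_edges=bin_edges, counts=counts)


class DnaFitError(RuntimeError):
    """The G1 peak could not be located or the fit failed."""


@dataclasses.dataclass(frozen=True)
class DnaMixtureResults:
    """Fit results: cycle fractions plus shape parameters and diagnostics."""

    fractions: CycleFractions
    mu: float
    cv: float
    rss: float
    n_events: int
    fitted_counts: np.ndarray

    @property
    def resid_rms(self) -> float:
        return float(np.sqrt(self.rss / self.fitted_counts.size))

    def summary(self) -> str:
        f = self.fractions
        lines = [
            "DNA-content mixture fit",
            "=" * 38,
            f"events            {self.n_events:>10d}",
            f"G1 peak location  {self.mu:>10.2f}",
            f"shared CV         {self.cv:>10.4f}",
            f"G1/G0 fraction    {f.g1_g0:>10.4f}",
            f"S fraction        {f.s:>10.4f}",
            f"G2/M fraction     {f.g2m:>10.4f}",
            f"residual RMS      {self.resid_rms:>10.3f}",
        ]
        return "\n".join(lines)


class DnaMixtureModel:
    """Least-squares mixture model for a DNA-content histogram.

    The G2/M location is hard-constrained to twice the G1 location and the
    coefficient of variation is shared across phases, which keeps the fit
    well-posed at moderate event counts.
    """

    def __init__(self, hist: DnaHistogram):
        if hist.n_events < MIN_EVENTS_FOR_FIT:
            raise ValueError(
                f"need at least {MIN_EVENTS_FOR_FIT} events, got {hist.n_events}"
            )
        self.hist = hist

    def _initial_mu(self) -> float:
        counts, centers = self.hist.counts, self.hist.centers
        if counts.max() <= 0:
            raise DnaFitError("empty histogram: cannot locate the G1 peak")
        # light smoothing so a noisy bin cannot masquerade as the peak
        kernel = np.ones(5) / 5.0
        smooth = np.convolve(counts, kernel, mode="same")
        mu0 = float(centers[np.argmax(smooth)])
        if mu0 <= self.hist.bin_edges[0] or mu0 >= self.hist.bin_edges[-1] / 1.5:
            raise DnaFitError(
                "G1 peak location implausible; histogram may not span both peaks"
            )
        return mu0

    def fit(self, cv0: float = 0.05) -> DnaMixtureResults:
        hist = self.hist
        mu0 = self._initial_mu()
        n = float(hist.counts.sum())

        # crude initial mass split around the two peak positions
        centers = hist.centers
        g1_mass = hist.counts[np.abs(centers - mu0) < 0.25 * mu0].sum() / n
        g2_mass = hist.counts[np.abs(centers - 2 * mu0) < 0.25 * mu0].sum() / n
        s_mass = max(1.0 - g1_mass - g2_mass, 1e-3)

        def model_counts(params):
            mu, cv, a1, a2, a3 = params
            probs = _phase_bin_probs(hist.bin_edges, mu, cv)
            amps = np.array([a1, a2, a3])
            return n * (amps / amps.sum()) @ probs

        def residuals(params):
            return model_counts(params) - hist.counts

        x0 = [mu0, cv0, max(g1_mass, 1e-3), s_mass, max(g2_mass, 1e-3)]
        lower = [0.6 * mu0, 0.005, 1e-6, 1e-6, 1e-6]
        upper = [1.4 * mu0, 0.2, 1.0, 1.0, 1.0]
        sol = optimize.least_squares(residuals, x0, bounds=(lower, upper))
        if not sol.success:
            raise DnaFitError(f"least-squares fit failed: {sol.message}")
        mu, cv, a1, a2, a3 = sol.x
        amps = np.array([a1, a2, a3])
        fracs = amps / amps.sum()
        fractions = CycleFractions(
            g1_g0=float(fracs[0]), s=float(fracs[1]), g2m=float(fracs[2])
        )
        return DnaMixtureResults(
            fractions=fractions,
            mu=float(mu),
            cv=float(cv),
            rss=float(np.sum(sol.fun**2)),
            n_events=hist.n_events,
            fitted_counts=model_counts(sol.x),
        )


def fit_dna_mixture(hist: DnaHistogram) -> CycleFractions:
    """Convenience wrapper: fit and return the cycle fractions only."""
    return DnaMixtureModel(hist).fit().fractions
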