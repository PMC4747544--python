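"""Reversible-jump MCMC over background-plus-hotspot recombination maps.

The model state is (theta, background rho/Mb, hotspot set).  Hotspots arrive
as a homogeneous Poisson process along the region (intensity
``hotspot_rate_per_mb``), with uniform widths, log-uniform intensity
multipliers, an exponential prior on the background rate and a log-uniform
prior on theta.  The sampler mixes birth/death (add/remove) reversible-jump
moves with within-model moves (translate, resize, rescale intensity,
background and theta), Metropolis-Hastings throughout.

Running the identical sampler with a constant likelihood ("prior mode", no
data) yields the prior bin-occupancy probabilities needed for Bayes-factor
calibration downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .simulate import Hotspot

_LOG_ZERO = -math.inf


@dataclass(frozen=True)
class PriorSpec:
    """Proper, weakly informative priors on the rate-map parameters.

    hotspot_rate_per_mb : expected hotspot count per Mb (Poisson arrivals).
    width bounds in bp (uniform); intensity bounds (log-uniform multiplier);
    background_mean in rho/Mb (exponential); theta bounds per site
    (log-uniform).
    """

    hotspot_rate_per_mb: float = 1.0
    width_min: float = 500.0
    width_max: float = 5_000.0
    intensity_min: float = 5.0
    intensity_max: float = 500.0
    background_mean: float = 100.0
    theta_min: float = 1e-4
    theta_max: float = 1e-2

    def expected_count(self, region_length: float) -> float:
        return self.hotspot_rate_per_mb * region_length / 1e6

    def sample_hotspot(self, rng, region_length: float) -> Hotspot:
        w = rng.uniform(self.width_min, self.width_max)
        start = rng.uniform(0.0, region_length - w)
        lam = math.exp(rng.uniform(math.log(self.intensity_min),
                                   math.log(self.intensity_max)))
        return Hotspot(start, start + w, lam)

    def log_hotspot_density(self, h: Hotspot, region_length: float) -> float:
        w = h.width
        if not (self.width_min <= w <= self.width_max):
            return _LOG_ZERO
        if not (0.0 <= h.start and h.end <= region_length):
            return _LOG_ZERO
        if not (self.intensity_min <= h.intensity <= self.intensity_max):
            return _LOG_ZERO
        return (-math.log(self.width_max - self.width_min)
                - math.log(region_length - w)
                - math.log(h.intensity)
                - math.log(math.log(self.intensity_max / self.intensity_min)))

    def log_background_density(self, b: float) -> float:
        if b < 0:
            return _LOG_ZERO
        return -math.log(self.background_mean) - b / self.background_mean

    def log_theta_density(self, t: float) -> float:
        if not (self.theta_min <= t <= self.theta_max):
            return _LOG_ZERO
        return -math.log(t) - math.log(math.log(self.theta_max / self.theta_min))

    def sample_state(self, rng, region_length: float) -> "ModelState":
        k = rng.poisson(self.expected_count(region_length))
        hs = tuple(self.sample_hotspot(rng, region_length) for _ in range(k))
        b = rng.exponential(self.background_mean)
        t = math.exp(rng.uniform(math.log(self.theta_min),
                                 math.log(self.theta_max)))
        return ModelState(t, b, hs)


@dataclass(frozen=True)
class ModelState:
    """One point in the (theta, background, hotspot set) parameter space."""

    theta: float
    background_rho_per_mb: float
    hotspots: tuple = ()

    def log_prior(self, prior: PriorSpec, region_length: float) -> float:
        lam = prior.expected_count(region_length)
        k = len(self.hotspots)
        lp = -lam + k * math.log(lam) if lam > 0 else (0.0 if k == 0 else _LOG_ZERO)
        # exchangeable-set convention: no k! term (cancels in RJ ratios)
        for h in self.hotspots:
            lp += prior.log_hotspot_density(h, region_length)
        lp += prior.log_background_density(self.background_rho_per_mb)
        lp += prior.log_theta_density(self.theta)
        return lp


DEFAULT_MOVE_WEIGHTS = {
    "add": 0.15, "remove": 0.15, "move": 0.20, "resize": 0.15,
    "intensity": 0.15, "background": 0.10, "theta": 0.10,
}

#: proposal scales tuned in preliminary runs to 20-50% acceptance
DEFAULT_PROPOSAL_SCALES = {
    "move_sd_bp": 1_000.0, "resize_log_sd": 0.3, "intensity_log_sd": 0.4,
    "background_log_sd": 0.25, "theta_log_sd": 0.3,
}


@dataclass(frozen=True)
class ChainSettings:
    """MCMC run configuration; thinning defaults so that roughly 2000
    post-thinning samples are recorded (first half then discarded as
    burn-in, leaving ~1000-2000 usable draws depending on run length)."""

    iterations: int = 20_000
    seed: int = 0
    thin: int = None  # type: ignore[assignment]
    burn_in_fraction: float = 0.5
    move_weights: dict = field(default_factory=lambda: dict(DEFAULT_MOVE_WEIGHTS))
    proposal_scales: dict = field(
        default_factory=lambda: dict(DEFAULT_PROPOSAL_SCALES))

    def __post_init__(self):
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")
        if not (0.0 < self.burn_in_fraction < 1.0):
            raise ValueError("burn-in fraction must lie in (0, 1)")
        if self.thin is None:
            object.__setattr__(self, "thin",
                               max(1, self.iterations // 4000))


@dataclass(frozen=True)
class PosteriorSample:
    """One thinned post-burn-in draw of the model state."""

    iteration: int
    theta: float
    background_rho_per_mb: float
    hotspots: tuple


@dataclass
class ChainDiagnostics:
    acceptance: dict
    proposed: dict
    n_recorded: int
    n_burned: int
    seed: int

    def acceptance_rates(self) -> dict:
        return {m: (self.acceptance[m] / self.proposed[m]
                    if self.proposed[m] else float("nan"))
                for m in self.proposed}


class RJSampler:
    """Metropolis-Hastings sampler with reversible-jump hotspot moves.

    ``engine`` must expose ``loglik_state(state) -> float``; use
    :class:`rhomap.likelihood.ConstantLikelihood` for prior mode.
    """

    def __init__(self, engine, region_length: float, prior: PriorSpec,
                 settings: ChainSettings):
        self.engine = engine
        self.L = float(region_length)
        self.prior = prior
        self.settings = settings
        self.rng = np.random.default_rng(settings.seed)
        self._moves = list(settings.move_weights)
        w = np.array([settings.move_weights[m] for m in self._moves], float)
        self._move_probs = w / w.sum()

    # -- reversible-jump log acceptance ratios (likelihood excluded) -------
    def log_accept_add(self, state: ModelState, h: Hotspot) -> float:
        """Birth move: h drawn from the hotspot prior; remove picks
        uniformly, so prior and proposal densities cancel except for the
        Poisson count ratio and the move-weight ratio."""
        lam = self.prior.expected_count(self.L)
        if lam == 0 or self.prior.log_hotspot_density(h, self.L) == _LOG_ZERO:
            return _LOG_ZERO
        k = len(state.hotspots)
        w = self.settings.move_weights
        return math.log(lam / (k + 1)) + math.log(w["remove"] / w["add"])

    def log_accept_remove(self, state: ModelState) -> float:
        """Death move (uniform choice among k hotspots); exact inverse of
        the birth ratio."""
        k = len(state.hotspots)
        if k == 0:
            return _LOG_ZERO
        lam = self.prior.expected_count(self.L)
        w = self.settings.move_weights
        return math.log(k / lam) + math.log(w["add"] / w["remove"])

    # -- proposal constructors --------------------------------------------
    def _propose(self, state: ModelState, move: str):
        """Return (new_state, log_hastings_plus_jump_terms) or None."""
        rng = self.rng
        sc = self.settings.proposal_scales
        hs = state.hotspots
        if move == "add":
            if self.prior.expected_count(self.L) == 0:
                return None
            h = self.prior.sample_hotspot(rng, self.L)
            new = replace(state, hotspots=hs + (h,))
            return new, self.log_accept_add(state, h)
        if move == "remove":
            if not hs:
                return None
            i = int(rng.integers(len(hs)))
            new = replace(state, hotspots=hs[:i] + hs[i + 1:])
            return new, self.log_accept_remove(state)
        if move in ("move", "resize", "intensity"):
            if not hs:
                return None
            i = int(rng.integers(len(hs)))
            h = hs[i]
            if move == "move":
                delta = rng.normal(0.0, sc["move_sd_bp"])
                start, end = h.start + delta, h.end + delta
                if start < 0 or end > self.L:
                    return None
                h2 = Hotspot(start, end, h.intensity)
                log_ratio = 0.0  # symmetric translation, width unchanged
            elif move == "resize":
                w2 = h.width * math.exp(rng.normal(0.0, sc["resize_log_sd"]))
                if not (self.prior.width_min <= w2 <= self.prior.width_max):
                    return None
                c = 0.5 * (h.start + h.end)
                start, end = c - w2 / 2.0, c + w2 / 2.0
                if start < 0 or end > self.L:
                    return None
                h2 = Hotspot(start, end, h.intensity)
                # uniform-centre prior density ratio + log-scale Hastings
                log_ratio = (math.log((self.L - h.width) / (self.L - w2))
                             + math.log(w2 / h.width))
            else:
                lam2 = h.intensity * math.exp(
                    rng.normal(0.0, sc["intensity_log_sd"]))
                if not (self.prior.intensity_min <= lam2
                        <= self.prior.intensity_max):
                    return None
                h2 = Hotspot(h.start, h.end, lam2)
                log_ratio = 0.0  # log-uniform prior cancels log-scale Hastings
            new = replace(state, hotspots=hs[:i] + (h2,) + hs[i + 1:])
            return new, log_ratio
        if move == "background":
            b = state.background_rho_per_mb
            b2 = b * math.exp(rng.normal(0.0, sc["background_log_sd"]))
            log_ratio = ((b - b2) / self.prior.background_mean
                         + math.log(b2 / b))
            return replace(state, background_rho_per_mb=b2), log_ratio
        if move == "theta":
            t2 = state.theta * math.exp(rng.normal(0.0, sc["theta_log_sd"]))
            if not (self.prior.theta_min <= t2 <= self.prior.theta_max):
                return None
            return replace(state, theta=t2), 0.0
        raise ValueError(f"unknown move {move!r}")

    # -- main loop ----------------------------------------------------------
    def run(self, init: ModelState = None
            ) -> tuple[list[PosteriorSample], ChainDiagnostics]:
        st = self.settings
        rng = self.rng
        state = init if init is not None else ModelState(
            theta=math.sqrt(self.prior.theta_min * self.prior.theta_max),
            background_rho_per_mb=self.prior.background_mean,
            hotspots=())
        loglik = self.engine.loglik_state(state)
        if not np.isfinite(loglik) or not np.isfinite(
                state.log_prior(self.prior, self.L)):
            raise RuntimeError(
                f"non-finite posterior at initialization: loglik={loglik}, "
                f"state={state}")
        proposed = {m: 0 for m in self._moves}
        accepted = {m: 0 for m in self._moves}
        recorded: list[PosteriorSample] = []
        for it in range(1, st.iterations + 1):
            move = self._moves[int(rng.choice(len(self._moves),
                                              p=self._move_probs))]
            prop = self._propose(state, move)
            if prop is not None:
                proposed[move] += 1
                new, log_ratio = prop
                new_loglik = self.engine.loglik_state(new)
                log_alpha = new_loglik - loglik + log_ratio
                if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
                    state, loglik = new, new_loglik
                    accepted[move] += 1
            if it % st.thin == 0:
                recorded.append(PosteriorSample(
                    it, state.theta, state.background_rho_per_mb,
                    state.hotspots))
        n_burn = int(len(recorded) * st.burn_in_fraction)
        samples = recorded[n_burn:]
        diag = ChainDiagnostics(accepted, proposed, len(recorded), n_burn,
                                st.seed)
        return samples, diag


def run_mcmc(engine, region_length: float, prior: PriorSpec,
             settings: ChainSettings, init: ModelState = None):
    """Run the reversible-jump chain; returns (samples, diagnostics)."""
    return RJSampler(engine, region_length, prior, settings).run(init)


def run_prior_chain(region_length: float, prior: PriorSpec,
                    settings: ChainSettings):
    """Identical sampler with likelihood held constant ("no data" mode);
    sample size and marker positions do not enter because the composite
    likelihood is switched off wholesale."""
    from .likelihood import ConstantLikelihood

    return RJSampler(ConstantLikelihood(), region_length, prior,
                     settings).run()
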