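"""Gaussian-process Bayesian optimisation over the stimulus grid, and the
closed-loop session runner.

The surrogate is a Gaussian process with a Matern kernel (smoothness
``nu = 2.5``) over grid coordinates normalised to the unit square, plus an
additive white-noise term; hyperparameters are fitted by maximising the log
marginal likelihood.  The acquisition function is expected improvement with
an exploration margin ``xi = 0.1`` (a small margin that favours exploitation
of the identified maximum).  The optimiser works on the sign-flipped Nc
negativity scale, so *maximising* the surrogate targets the most negative
Nc deflection.

A session presents the four corner burn-ins, then acquisition-selected
stimuli, one simulated and preprocessed 12-trial block at a time.  Blocks
failing the 16 % validity gate are re-presented with the same stimulus (they
count toward the 15-block cap but yield no observation; more than three
consecutive failures abort the session).  The session converges when the
same stimulus is chosen three times in a row, burn-ins included; otherwise
it stops at 15 presented blocks and reports the posterior-mean argmax.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from . import ncmetric, preproc, synth
from .stimspace import (
    BurnInSchedule,
    StimulusCoord,
    burn_in_sequence,
    distance_from_reference,
    grid,
    quadrant_of,
)

GRID = grid()
#: grid coordinates normalised to the unit square for kernel evaluation
GRID_X = np.array([[c.emotion_idx / 3.0, c.gaze_idx / 3.0] for c in GRID])


@dataclass(frozen=True)
class GPConfig:
    """Matern-5/2 + white-noise surrogate configuration.

    Two bounds encode prior knowledge about the 4x4 grid:

    * the length-scale floor is one grid step (1/3 in normalised units) —
      structure finer than the grid spacing is unidentifiable from 16 cells;
    * the white-noise variance floor of 0.09 uV^2 encodes that a single-block
      Nc estimate always carries at least ~0.3 uV of measurement error.  It
      keeps the posterior sd at observed cells positive, so that expected
      improvement can re-select (and thereby converge on) the incumbent
      instead of exploring indefinitely once the data look noiseless.
    """

    length_scale: float = 0.5
    length_scale_bounds: tuple[float, float] = (1.0 / 3.0, 5.0)
    signal_variance: float = 1.0
    signal_variance_bounds: tuple[float, float] = (1e-3, 1e3)
    noise_variance: float = 0.1
    noise_variance_bounds: tuple[float, float] = (0.09, 1e2)
    n_restarts: int = 2
    seed: int = 0

    def kernel(self):
        return (
            ConstantKernel(self.signal_variance, self.signal_variance_bounds)
            * Matern(self.length_scale, self.length_scale_bounds, nu=2.5)
            + WhiteKernel(self.noise_variance, self.noise_variance_bounds)
        )


@dataclass(frozen=True)
class AcquisitionConfig:
    kind: str = "expected-improvement"
    xi: float = 0.1
    tie_break: str = "lowest-index"  # or "seeded-random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.xi < 0:
            raise ValueError("xi must be >= 0")


@dataclass(frozen=True)
class Observation:
    stimulus: StimulusCoord
    value: float  # Nc negativity, sign-flipped scale
    block_index: int


@dataclass
class GPPosterior:
    mean: np.ndarray  # (16,)
    sd: np.ndarray  # (16,)
    log_marginal_likelihood: float
    fallback: bool = False
    model: GaussianProcessRegressor | None = None


def fit_surrogate(
    observations: list[Observation], gp_config: GPConfig = GPConfig()
) -> GPPosterior:
    """Fit the GP to the observations and predict over all 16 cells.

    Hyperparameters maximise the log marginal likelihood over
    ``n_restarts`` seeded starts.  A degenerate fit (non-finite LML) falls
    back to the prior with the default hyperparameters, flagged.
    """
    if not observations:
        raise ValueError("at least one observation is required")
    X = np.array(
        [[o.stimulus.emotion_idx / 3.0, o.stimulus.gaze_idx / 3.0]
         for o in observations]
    )
    y = np.array([o.value for o in observations])

    def _predict(gpr: GaussianProcessRegressor) -> tuple[np.ndarray, np.ndarray]:
        mean, sd = gpr.predict(GRID_X, return_std=True)
        return np.asarray(mean), np.asarray(sd)

    gpr = GaussianProcessRegressor(
        kernel=gp_config.kernel(),
        n_restarts_optimizer=max(gp_config.n_restarts - 1, 0),
        normalize_y=True,
        random_state=gp_config.seed,
    )
    try:
        with warnings.catch_warnings():
            # hitting the deliberate noise/length-scale floors is expected
            warnings.simplefilter("ignore", ConvergenceWarning)
            gpr.fit(X, y)
        lml = float(gpr.log_marginal_likelihood_value_)
        if not np.isfinite(lml):
            raise ValueError("non-finite log marginal likelihood")
        mean, sd = _predict(gpr)
        return GPPosterior(mean=mean, sd=sd, log_marginal_likelihood=lml,
                           model=gpr)
    except (ValueError, np.linalg.LinAlgError):
        prior = GaussianProcessRegressor(
            kernel=gp_config.kernel(), optimizer=None, normalize_y=True,
        )
        prior.fit(X, y)
        mean, sd = _predict(prior)
        lml = float(prior.log_marginal_likelihood_value_)
        return GPPosterior(mean=mean, sd=sd, log_marginal_likelihood=lml,
                           fallback=True, model=prior)


def expected_improvement(
    mean: np.ndarray, sd: np.ndarray, best_observed: float, xi: float = 0.1
) -> np.ndarray:
    """EI per cell: ``delta * Phi(z) + sd * phi(z)`` with
    ``delta = mean - best_observed - xi`` and ``z = delta / sd``; for
    ``sd == 0`` it degenerates to ``max(delta, 0)``."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if (sd < 0).any():
        raise ValueError("sd must be >= 0")
    delta = mean - best_observed - xi
    ei = np.maximum(delta, 0.0)
    pos = sd > 0
    z = np.zeros_like(delta)
    z[pos] = delta[pos] / sd[pos]
    ei = np.where(pos, delta * norm.cdf(z) + sd * norm.pdf(z), ei)
    return ei


def select_next(
    posterior: GPPosterior,
    observations: list[Observation],
    acq_config: AcquisitionConfig = AcquisitionConfig(),
) -> StimulusCoord:
    """Argmax of expected improvement over the 16 cells.

    Exact ties are broken by lowest ``(emotion_idx, gaze_idx)`` (the grid's
    lexicographic order) or by a seeded random draw among the tied cells.
    """
    best = max(o.value for o in observations)
    ei = expected_improvement(posterior.mean, posterior.sd, best, acq_config.xi)
    if acq_config.tie_break == "seeded-random":
        ties = np.flatnonzero(ei == ei.max())
        rng = np.random.default_rng([acq_config.seed, len(observations)])
        return GRID[int(rng.choice(ties))]
    return GRID[int(np.argmax(ei))]


def check_convergence(presented: list[StimulusCoord]) -> bool:
    """True iff the last three chosen stimuli are identical (burn-ins count)."""
    return len(presented) >= 3 and presented[-1] == presented[-2] == presented[-3]


@dataclass
class BlockLog:
    block: int
    stimulus: str
    valid_fraction: float
    criteria_mode: str
    nc_negativity: float | None = None
    nc_mean_amplitude: float | None = None
    early_mean_amplitude: float | None = None
    gp_mean: list[float] | None = None
    gp_sd: list[float] | None = None
    ei: list[float] | None = None
    converged_flag: bool = False

    def to_json(self) -> str:
        record = {"schema_version": 1, **self.__dict__}
        return json.dumps(record)


@dataclass
class SessionResult:
    converged: bool
    optimum: StimulusCoord | None
    n_blocks_presented: int
    observations: list[Observation]
    trajectory: list[BlockLog]
    criteria_mode: str
    aborted: bool = False
    infant_seed: int | None = None

    @property
    def distance_from_veryhappy0(self) -> float | None:
        if self.optimum is None:
            return None
        return distance_from_reference(self.optimum)

    @property
    def quadrant(self) -> str | None:
        return None if self.optimum is None else quadrant_of(self.optimum)

    @property
    def mean_valid_fraction(self) -> float:
        return float(np.mean([b.valid_fraction for b in self.trajectory]))

    def write_jsonl(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for rec in self.trajectory:
                fh.write(rec.to_json() + "\n")
            fh.write(json.dumps({
                "schema_version": 1,
                "session_summary": True,
                "converged": self.converged,
                "aborted": self.aborted,
                "optimum": None if self.optimum is None else self.optimum.label,
                "n_blocks_presented": self.n_blocks_presented,
                "criteria_mode": self.criteria_mode,
                "distance_from_veryhappy0": self.distance_from_veryhappy0,
                "quadrant": self.quadrant,
                "infant_seed": self.infant_seed,
            }) + "\n")
        return path


def _posterior_argmax(posterior: GPPosterior) -> StimulusCoord:
    return GRID[int(np.argmax(posterior.mean))]


def run_session(
    infant: synth.InfantProfile,
    burn_in: BurnInSchedule | None = None,
    gp_config: GPConfig = GPConfig(),
    acq_config: AcquisitionConfig = AcquisitionConfig(),
    preprocess_config: preproc.PreprocessConfig = preproc.PreprocessConfig(),
    max_blocks: int = 15,
    max_repeats: int = 3,
    select_fn=None,
) -> SessionResult:
    """Run one closed-loop session against a simulated infant.

    ``select_fn(posterior, observations, acq_config)`` may replace the
    acquisition rule (used for diagnostics).  A session is a pure function
    of the infant profile and the configuration seeds.
    """
    if burn_in is None:
        burn_in = burn_in_sequence("fixed")
    select = select_fn or select_next

    choices: list[StimulusCoord] = []
    observations: list[Observation] = []
    trajectory: list[BlockLog] = []
    criteria = preproc.ArtifactCriteria.less_conservative()
    criteria_selected = False
    pending: StimulusCoord | None = None
    consecutive_invalid = 0
    presented = 0
    converged = False
    aborted = False
    optimum: StimulusCoord | None = None

    while presented < max_blocks:
        posterior = None
        if pending is not None:
            stim = pending
        elif len(choices) < len(burn_in.sequence):
            stim = burn_in.sequence[len(choices)]
        else:
            posterior = fit_surrogate(observations, gp_config)
            stim = select(posterior, observations, acq_config)

        recording = synth.simulate_block(infant, stim, presented + 1)
        block = preproc.process_block(recording, criteria, preprocess_config)
        presented += 1

        if not criteria_selected and block.erp is not None:
            # the first analysable block fixes the session criteria; it is
            # not re-processed under the newly selected set
            criteria = preproc.select_criteria(block.erp)
            criteria_selected = True

        log = BlockLog(
            block=presented,
            stimulus=stim.label,
            valid_fraction=block.valid_fraction,
            criteria_mode=block.criteria_used.mode,
        )
        if posterior is not None:
            best = max(o.value for o in observations)
            log.gp_mean = [float(v) for v in posterior.mean]
            log.gp_sd = [float(v) for v in posterior.sd]
            log.ei = [float(v) for v in expected_improvement(
                posterior.mean, posterior.sd, best, acq_config.xi)]

        if block.is_valid:
            metrics = ncmetric.block_metrics(block.erp)
            log.nc_negativity = metrics["nc_negativity"]
            log.nc_mean_amplitude = metrics["nc_mean_amplitude"]
            log.early_mean_amplitude = metrics["early_mean_amplitude"]
            observations.append(
                Observation(stimulus=stim, value=metrics["nc_negativity"],
                            block_index=presented)
            )
            choices.append(stim)
            pending = None
            consecutive_invalid = 0
            if check_convergence(choices):
                converged = True
                optimum = stim
                log.converged_flag = True
                trajectory.append(log)
                break
        else:
            pending = stim
            consecutive_invalid += 1
            if consecutive_invalid > max_repeats:
                aborted = True
                trajectory.append(log)
                break
        trajectory.append(log)

    if not converged and not aborted and observations:
        posterior = fit_surrogate(observations, gp_config)
        optimum = _posterior_argmax(posterior)
    elif aborted:
        optimum = None

    return SessionResult(
        converged=converged,
        optimum=optimum,
        n_blocks_presented=presented,
        observations=observations,
        trajectory=trajectory,
        criteria_mode=criteria.mode,
        aborted=aborted,
        infant_seed=infant.seed,
    )


def read_session_jsonl(path: str | Path) -> SessionResult:
    """Rebuild a session summary from a JSON-lines log (replay input)."""
    blocks: list[BlockLog] = []
    summary = None
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            if rec.get("session_summary"):
                summary = rec
            else:
                rec.pop("schema_version", None)
                blocks.append(BlockLog(**rec))
    if summary is None:
        raise ValueError(f"no session summary record in {path}")
    observations = [
        Observation(StimulusCoord.from_label(b.stimulus), b.nc_negativity, b.block)
        for b in blocks
        if b.nc_negativity is not None
    ]
    optimum = (None if summary["optimum"] is None
               else StimulusCoord.from_label(summary["optimum"]))
    return SessionResult(
        converged=summary["converged"],
        optimum=optimum,
        n_blocks_presented=summary["n_blocks_presented"],
        observations=observations,
        trajectory=blocks,
        criteria_mode=summary["criteria_mode"],
        aborted=summary.get("aborted", False),
        infant_seed=summary.get("infant_seed"),
    )
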