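"""The closed active-learning loop, end to end.

One campaign iteration: choose a batch of compositions (random for the
first iteration, acquisition-driven afterwards), observe each through the
virtual laboratory (direct binomial sampling or the full image-and-detect
route), refit the GP surrogate on all data collected so far, evaluate the
posterior on a fixed monitoring grid, and append the KL-based convergence
record. The loop runs a fixed iteration budget; KL-based early stopping
is evaluated every iteration but only acts when explicitly enabled.

Seed discipline: a single master seed spawns an independent, addressable
stream per (iteration, component) — batch selection, observation, fitting
and imaging never share draws, so any iteration can be reproduced in
isolation and a resumed campaign continues exactly where a straight
-through run would have been.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import acquisition, convergence, surrogate, virtual_lab
from .acquisition import AcquisitionConfig
from .convergence import ConvergenceTrace
from .design_space import (
    DesignSpace,
    balance_counter,
    flows_to_concentrations,
    make_grid,
    random_batch,
)
from .errors import ConfigMismatch, CorruptState
from .surrogate import PosteriorField, SurrogateState, field_to_dataframe
from .virtual_lab import ObservedSample, PhaseModel

logger = logging.getLogger("phasemap")

# stream identifiers for per-iteration child seeds
_STREAM_BATCH = 0
_STREAM_OBSERVE = 1
_STREAM_FIT = 2


@dataclass(frozen=True)
class CampaignConfig:
    """Everything needed to run (and re-run) a campaign."""

    space: DesignSpace
    model: PhaseModel
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    droplet_range: tuple[int, int] = (50, 250)
    observation_mode: str = "direct"  # or "imaged"
    render_spec: object | None = None
    n_iterations: int = 10
    monitor_resolution: int = 21
    convergence_threshold: float = 1.0
    patience: int = 2
    early_stop: bool = False
    master_seed: int = 0
    n_restarts: int = 25
    noise_level: float | str | None = None  # None: 0 (interpolating GP); "binomial": y(1-y)/n per sample
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.monitor_resolution < 2:
            raise ValueError("monitor_resolution must be >= 2")
        if self.observation_mode not in ("direct", "imaged"):
            raise ValueError("observation_mode must be 'direct' or 'imaged'")
        if not self.space.always_balanceable:
            raise ValueError(
                "campaign design space must satisfy sum(flow_max) <= total_flow "
                "so every sampled composition can be counter-balanced"
            )

    def observation_noise(self, y: np.ndarray, n_droplets: np.ndarray):
        """Observation-noise variance used in campaign refits.

        Default (None) is 0: a near-interpolating GP with diagonal
        jitter only, no white-noise term. ``"binomial"`` instead charges
        each sample its estimated binomial fraction variance y(1-y)/n —
        recommended when many observations fall near the boundary, where
        replicate noise is largest and interpolation shrinks the length
        scales onto it. A float gives a homoscedastic level.
        """
        if self.noise_level is None:
            return 0.0
        if self.noise_level == "binomial":
            return y * (1.0 - y) / np.asarray(n_droplets, dtype=float)
        return float(self.noise_level)

    def to_dict(self) -> dict:
        return {
            "space": self.space.to_dict(),
            "model": self.model.to_dict(),
            "acquisition": self.acquisition.to_dict(),
            "droplet_range": list(self.droplet_range),
            "observation_mode": self.observation_mode,
            "n_iterations": self.n_iterations,
            "monitor_resolution": self.monitor_resolution,
            "convergence_threshold": self.convergence_threshold,
            "patience": self.patience,
            "early_stop": self.early_stop,
            "master_seed": self.master_seed,
            "n_restarts": self.n_restarts,
            "noise_level": self.noise_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CampaignConfig":
        return cls(
            space=DesignSpace.from_dict(d["space"]),
            model=PhaseModel(
                kind=d["model"]["kind"],
                weights=tuple(d["model"]["weights"]),
                offset=d["model"]["offset"],
                steepness=d["model"]["steepness"],
            ),
            acquisition=AcquisitionConfig(**d.get("acquisition", {})),
            droplet_range=tuple(d.get("droplet_range", (50, 250))),
            observation_mode=d.get("observation_mode", "direct"),
            n_iterations=d.get("n_iterations", 10),
            monitor_resolution=d.get("monitor_resolution", 21),
            convergence_threshold=d.get("convergence_threshold", 1.0),
            patience=d.get("patience", 2),
            early_stop=d.get("early_stop", False),
            master_seed=d.get("master_seed", 0),
            n_restarts=d.get("n_restarts", 25),
            noise_level=d.get("noise_level"),
        )

    @classmethod
    def from_yaml(cls, path) -> "CampaignConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class CampaignState:
    """Full loop history of one campaign."""

    config: CampaignConfig
    samples: list[tuple[int, int, ObservedSample]] = field(default_factory=list)
    surrogate_states: list[SurrogateState] = field(default_factory=list)
    trace: ConvergenceTrace = field(default_factory=ConvergenceTrace)
    termination: str = "incomplete"
    completed_iterations: int = 0
    last_field: PosteriorField | None = None

    # -- views ------------------------------------------------------------

    @property
    def final_surrogate(self) -> SurrogateState:
        return self.surrogate_states[-1]

    def training_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        X = np.array([s.composition.flows for _, _, s in self.samples])
        y = np.array([s.ps_fraction for _, _, s in self.samples])
        n = np.array([s.n_droplets_analyzed for _, _, s in self.samples])
        return X, y, n

    def samples_dataframe(self) -> pd.DataFrame:
        space = self.config.space
        rows = []
        for iteration, order, s in self.samples:
            row = {"iteration": iteration, "order": order}
            for name, f in zip(space.names, s.composition.flows):
                row[f"flow_{name}"] = f
            row["counter_flow"] = s.composition.counter_flow
            conc = flows_to_concentrations(s.composition, space)
            for name, c in zip(space.names, conc):
                row[f"conc_{name}"] = c
            row["n_droplets"] = s.n_droplets_analyzed
            row["n_ps"] = s.n_ps
            row["ps_fraction"] = s.ps_fraction
            rows.append(row)
        return pd.DataFrame(rows)

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.samples_dataframe().to_csv(directory / "samples.csv", index=False)
        self.trace.to_dataframe(self.config.space).to_csv(
            directory / "trace.csv", index=False
        )
        meta = {
            "config": self.config.to_dict(),
            "termination": self.termination,
            "completed_iterations": self.completed_iterations,
        }
        with open(directory / "state.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, directory) -> "CampaignState":
        directory = Path(directory)
        try:
            with open(directory / "state.json") as fh:
                meta = json.load(fh)
            config = CampaignConfig.from_dict(meta["config"])
            df = pd.read_csv(directory / "samples.csv")
        except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
            raise CorruptState(f"cannot load campaign state: {exc}") from exc
        state = cls(
            config=config,
            termination=meta.get("termination", "incomplete"),
            completed_iterations=int(meta.get("completed_iterations", 0)),
        )
        for _, row in df.iterrows():
            flows = np.array([row[f"flow_{n}"] for n in config.space.names])
            comp = balance_counter(flows, config.space)
            state.samples.append(
                (
                    int(row["iteration"]),
                    int(row["order"]),
                    ObservedSample(
                        composition=comp,
                        n_droplets_analyzed=int(row["n_droplets"]),
                        n_ps=int(row["n_ps"]),
                    ),
                )
            )
        return state


def _iteration_seed(master: int, iteration: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master), int(iteration), int(stream)])


def _fit_seed_int(master: int, iteration: int) -> int:
    ss = _iteration_seed(master, iteration, _STREAM_FIT)
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _observe_batch(
    cfg: CampaignConfig, flows_batch: np.ndarray, iteration: int
) -> list[ObservedSample]:
    rng = np.random.default_rng(_iteration_seed(cfg.master_seed, iteration, _STREAM_OBSERVE))
    out = []
    for flows in flows_batch:
        comp = balance_counter(flows, cfg.space)
        child = rng.integers(0, 2**31 - 1)
        if cfg.observation_mode == "direct":
            obs = virtual_lab.run_virtual_sample(
                cfg.model, comp, cfg.space, cfg.droplet_range, seed=child
            )
        else:
            obs = virtual_lab.run_virtual_sample_imaged(
                cfg.model,
                comp,
                cfg.space,
                render_spec=cfg.render_spec,
                droplet_range=cfg.droplet_range,
                seed=child,
            )
        out.append(obs)
    return out


def _fit_on(cfg: CampaignConfig, X, y, n_droplets, iteration: int, warm) -> SurrogateState:
    return surrogate.fit_surrogate(
        X,
        y,
        cfg.space,
        n_restarts=cfg.n_restarts,
        seed=_fit_seed_int(cfg.master_seed, iteration),
        noise_level=cfg.observation_noise(y, n_droplets),
        initial_kernel_state=warm,
    )


def _fit_iteration(cfg: CampaignConfig, state: CampaignState, iteration: int) -> SurrogateState:
    X, y, n = state.training_arrays()
    warm = state.surrogate_states[-1].kernel_state if state.surrogate_states else None
    return _fit_on(cfg, X, y, n, iteration, warm)


def _run_loop(cfg: CampaignConfig, state: CampaignState, until: int) -> CampaignState:
    """Advance ``state`` through iterations (state.completed_iterations, until]."""
    monitor_grid = make_grid(cfg.space, cfg.monitor_resolution)
    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for iteration in range(state.completed_iterations + 1, until + 1):
        try:
            if iteration == 1:
                batch = random_batch(
                    cfg.space,
                    cfg.acquisition.batch_size,
                    seed=_iteration_seed(cfg.master_seed, iteration, _STREAM_BATCH),
                )
            else:
                sel = acquisition.select_batch(
                    state.final_surrogate,
                    cfg.acquisition,
                    cfg.space,
                    seed=_iteration_seed(cfg.master_seed, iteration, _STREAM_BATCH),
                )
                batch = sel.points
            observations = _observe_batch(cfg, batch, iteration)
            for order, obs in enumerate(observations):
                state.samples.append((iteration, order, obs))

            fitted = _fit_iteration(cfg, state, iteration)
            state.surrogate_states.append(fitted)
            fld = surrogate.predict(fitted, monitor_grid)
            if state.last_field is not None:
                state.trace.append(
                    convergence.rss_kl(fld, state.last_field),
                    convergence.per_dimension_rss(fld, state.last_field, cfg.space),
                    fitted.kernel_state,
                )
            state.last_field = fld
            state.completed_iterations = iteration
            logger.info(
                "iteration %d: %d samples total, rss_kl=%s",
                iteration,
                len(state.samples),
                f"{state.trace.rss[-1]:.4g}" if len(state.trace) else "n/a",
            )
            if out_dir is not None:
                field_to_dataframe(fld, cfg.space).to_csv(
                    out_dir / f"posterior_iter_{iteration}.csv", index=False
                )
        except Exception:
            state.termination = f"error at iteration {iteration}"
            if out_dir is not None:
                out_dir.mkdir(parents=True, exist_ok=True)
                state.save(out_dir)
            logger.exception("campaign failed at iteration %d", iteration)
            raise

        if (
            cfg.early_stop
            and convergence.check_converged(
                state.trace.rss, cfg.convergence_threshold, cfg.patience
            )
        ):
            state.termination = f"converged at iteration {iteration}"
            break
    else:
        state.termination = "budget exhausted"

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        state.save(out_dir)
    return state


def run_campaign(cfg: CampaignConfig) -> CampaignState:
    """Run a full campaign from scratch. Deterministic for a fixed config."""
    state = CampaignState(config=cfg)
    return _run_loop(cfg, state, cfg.n_iterations)


def resume_campaign(
    state_dir, extra_iterations: int, expected_config: CampaignConfig | None = None
) -> CampaignState:
    """Continue a persisted campaign for ``extra_iterations`` more iterations.

    The per-iteration seed streams are addressed by the master seed and
    iteration index, so resuming reproduces exactly what a longer
    straight-through run would have done (direct observation mode).
    """
    state = CampaignState.load(state_dir)
    cfg = state.config
    if expected_config is not None and expected_config.space.to_dict() != cfg.space.to_dict():
        raise ConfigMismatch("design space differs from the persisted campaign")
    if extra_iterations < 0:
        raise ValueError("extra_iterations must be >= 0")
    if extra_iterations == 0:
        return state

    # replay the surrogate fit chain from the recorded samples: each
    # iteration's fit warm-starts from the previous one, so the whole
    # chain must be rebuilt for the continuation to match a straight
    # -through run (same seeds and same warm starts => same state)
    if state.completed_iterations >= 1:
        for k in range(1, state.completed_iterations + 1):
            upto = [s for it, _, s in state.samples if it <= k]
            X = np.array([s.composition.flows for s in upto])
            y = np.array([s.ps_fraction for s in upto])
            n = np.array([s.n_droplets_analyzed for s in upto])
            warm = state.surrogate_states[-1].kernel_state if state.surrogate_states else None
            state.surrogate_states.append(_fit_on(cfg, X, y, n, k, warm))
        grid = make_grid(cfg.space, cfg.monitor_resolution)
        state.last_field = surrogate.predict(state.surrogate_states[-1], grid)
        # trace history from disk
        trace_path = Path(state_dir) / "trace.csv"
        if trace_path.exists():
            tdf = pd.read_csv(trace_path)
            for _, row in tdf.iterrows():
                state.trace.append(
                    row["rss_kl"],
                    np.array([row[f"rss_kl_{n}"] for n in cfg.space.names]),
                    surrogate.KernelState(
                        amplitude=row["amplitude"],
                        length_scales=np.array(
                            [row[f"length_scale_{n}"] for n in cfg.space.names]
                        ),
                    ),
                )
    cfg = replace(cfg, n_iterations=state.completed_iterations + extra_iterations)
    state.config = cfg
    return _run_loop(cfg, state, cfg.n_iterations)


# -- strategy comparison -------------------------------------------------


def sampled_boundary_distance(state: CampaignState) -> float:
    """Median |true p - 0.5| over all sampled compositions (skips iter 1)."""
    cfg = state.config
    pts = np.array(
        [s.composition.flows for it, _, s in state.samples if it > 1]
    )
    if len(pts) == 0:
        pts = np.array([s.composition.flows for _, _, s in state.samples])
    p = virtual_lab.probability_at_flows(cfg.model, pts, cfg.space)
    return float(np.median(np.abs(p - 0.5)))


def mean_pairwise_spread(state: CampaignState) -> float:
    """Mean pairwise scaled distance between all sampled compositions."""
    pts = np.array([s.composition.flows for _, _, s in state.samples])
    z = (pts - state.config.space.lower) / state.config.space.ranges
    diff = z[:, None, :] - z[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    n = len(z)
    return float(d[np.triu_indices(n, k=1)].mean())


def compare_strategies(
    cfg: CampaignConfig, modes: list[str], n_seeds: int = 10, base_seed: int = 0
) -> pd.DataFrame:
    """Run the same campaign under several acquisition modes and seeds.

    Returns one row per (mode, seed) with the final RSS-KL, the boundary
    recovery error of the final surrogate, the median sampled-point
    distance from the true boundary, and the mean pairwise spread.
    """
    if len(modes) < 2:
        raise ValueError("need at least two modes to compare")
    rows = []
    for mode in modes:
        for i in range(n_seeds):
            run_cfg = replace(
                cfg,
                acquisition=replace(cfg.acquisition, mode=mode),
                master_seed=base_seed + i,
                output_dir=None,
            )
            state = run_campaign(run_cfg)
            rows.append(
                {
                    "mode": mode,
                    "seed": base_seed + i,
                    "final_rss_kl": state.trace.rss[-1] if len(state.trace) else np.nan,
                    "boundary_error": virtual_lab.boundary_recovery_error(
                        state.final_surrogate, cfg.model, cfg.space,
                        n_per_dim=cfg.monitor_resolution,
                    ),
                    "sampled_boundary_distance": sampled_boundary_distance(state),
                    "pairwise_spread": mean_pairwise_spread(state),
                }
            )
    return pd.DataFrame(rows)
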