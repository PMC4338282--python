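"""Monte Carlo run orchestration.

:class:`Simulation` owns a :class:`~segcpm.state.SimState` plus the adhesion
model, optional J-modification mechanism, optional persistence, and the RNG
stream.  The protocol of :meth:`Simulation.run` is:

1. initialization period (``init_period`` MCS): cells inflate from their 5x5
   seed blocks under the area constraint; persistence and measurement are
   suspended;
2. persistence (when configured) activates with fresh anchors and random
   target directions;
3. main loop to ``duration`` MCS, sampling centroids and tissue shape every
   ``measurement_interval`` MCS.

All randomness — kernel attempts and the initial target directions — derives
from the single ``SimConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel, metrics, motility
from .adhesion import Mechanism, kernel_mechanism_args
from .errors import ConfigurationError
from .params import AdhesionTable, Persistence, SimConfig
from .state import SimState

__all__ = ["Simulation", "RunResult", "run_simulation"]


@dataclass
class RunResult:
    """Outputs of one run: the final state, centroid tracks, tissue-shape
    time series and attempt/accept counters."""

    state: SimState
    tracks: pd.DataFrame      # columns: mcs, sigma, x, y
    shapes: pd.DataFrame      # columns: mcs, long_axis, short_axis, angle, cx, cy
    counters: dict = field(default_factory=dict)

    def initial_long_axis(self, at_mcs: int = 5000) -> float:
        """Tissue long-axis length at the reference sample (default MCS 5000,
        the first sample after inflation)."""
        row = self.shapes[self.shapes.mcs == at_mcs]
        if row.empty:
            raise ConfigurationError(f"no shape sample at MCS {at_mcs}")
        return float(row.long_axis.iloc[0])

    def final_long_axis(self, tail: float = 0.0) -> float:
        """Long-axis length at the end of the run; with ``tail`` in (0, 1),
        the mean over the last ``tail`` fraction of samples (suppresses
        thermal fluctuation noise once the shape has plateaued)."""
        if tail <= 0.0:
            return float(self.shapes.long_axis.iloc[-1])
        t0 = self.shapes.mcs.max() - tail * \
            (self.shapes.mcs.max() - self.shapes.mcs.min())
        return float(self.shapes.long_axis[self.shapes.mcs >= t0].mean())

    def elongation_fold(self, at_mcs: int = 5000, tail: float = 0.0) -> float:
        """final / initial long-axis length."""
        return self.final_long_axis(tail) / self.initial_long_axis(at_mcs)


class Simulation:
    """A configured, running CPM simulation (mutable)."""

    def __init__(self, state: SimState, adhesion: AdhesionTable,
                 config: SimConfig, mechanism: Mechanism = None,
                 persistence: Persistence | None = None) -> None:
        self.state = state
        self.adhesion = adhesion
        self.config = config
        self.mechanism = mechanism
        self.persistence = persistence
        seq = np.random.SeedSequence(config.seed)
        kernel_seed, py_seed = seq.spawn(2)
        self.rng_state = _kernel.seed_rng_state(
            int(kernel_seed.generate_state(1, np.uint64)[0]))
        self.py_rng = np.random.default_rng(py_seed)
        self.counters = np.zeros(3, dtype=np.int64)
        self.persistence_active = False

    # -- stepping ---------------------------------------------------------

    def advance(self, n_mcs: int) -> None:
        """Advance ``n_mcs`` Monte Carlo steps in place."""
        if n_mcs <= 0:
            return
        st = self.state
        mech, gauss_col, beta, mm = kernel_mechanism_args(self.mechanism,
                                                          st.width)
        pers = self.persistence
        pers_on = pers is not None and self.persistence_active
        _kernel.run_mcs(
            st.sites, st.area, st.target_area, st.ctype, st.conc_b,
            st.sum_x, st.sum_y, st.tdir_x, st.tdir_y,
            st.anchor_x, st.anchor_y,
            self.adhesion.matrix, float(self.config.lambda_area),
            float(self.config.temperature), mech, gauss_col, beta, mm,
            pers_on,
            float(pers.mu) * float(self.config.temperature) if pers else 0.0,
            int(pers.s) if pers else 1,
            bool(pers.bias_retraction) if pers else False,
            int(n_mcs), int(st.mcs), self.rng_state, self.counters)
        st.mcs += int(n_mcs)

    def _activate_persistence(self) -> None:
        if self.persistence is not None and not self.persistence_active:
            motility.init_target_directions(self.state, self.py_rng)
            self.persistence_active = True

    # -- full protocol ----------------------------------------------------

    def run(self, record: bool = True) -> RunResult:
        cfg = self.config
        interval = cfg.measurement_interval
        track_rows: list[tuple[int, int, float, float]] = []
        shape_rows: list[tuple[int, float, float, float, float, float]] = []

        def sample() -> None:
            if not record:
                return
            st = self.state
            cents = st.centroids()
            for sigma in np.nonzero(st.alive())[0]:
                track_rows.append((st.mcs, int(sigma),
                                   cents[sigma, 0], cents[sigma, 1]))
            ax = metrics.tissue_axes(st)
            cx, cy = metrics.tissue_centroid(st)
            shape_rows.append((st.mcs, ax.long_axis, ax.short_axis, ax.angle,
                               cx, cy))

        if self.state.mcs >= cfg.init_period:
            self._activate_persistence()
        if self.state.mcs == 0:
            sample()
        events = sorted({cfg.init_period, cfg.duration}
                        | set(range(interval, cfg.duration + 1, interval)))
        for t in events:
            if t <= self.state.mcs:
                continue
            self.advance(t - self.state.mcs)
            if t == cfg.init_period:
                self._activate_persistence()
            if t % interval == 0 or t == cfg.duration:
                sample()
        tracks = pd.DataFrame(track_rows, columns=["mcs", "sigma", "x", "y"])
        shapes = pd.DataFrame(shape_rows,
                              columns=["mcs", "long_axis", "short_axis",
                                       "angle", "cx", "cy"])
        counters = {"attempts": int(self.counters[0]),
                    "null_attempts": int(self.counters[1]),
                    "accepted": int(self.counters[2])}
        return RunResult(state=self.state, tracks=tracks, shapes=shapes,
                         counters=counters)

    # -- checkpointing ----------------------------------------------------

    def save(self, path) -> None:
        """Snapshot the full mutable state (lattice, bookkeeping, RNG) so a
        reloaded run continues bit-identically."""
        st = self.state
        arrays = {name: getattr(st, name) for name in SimState.CELL_ARRAYS}
        np.savez(path, sites=st.sites, mcs=np.int64(st.mcs),
                 rng_state=self.rng_state, counters=self.counters,
                 persistence_active=np.int8(self.persistence_active),
                 py_rng_state=np.frombuffer(
                     json.dumps(self.py_rng.bit_generator.state).encode(),
                     dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path, adhesion: AdhesionTable, config: SimConfig,
             mechanism: Mechanism = None,
             persistence: Persistence | None = None) -> "Simulation":
        data = np.load(path)
        sites = data["sites"]
        n_cells = int(data["area"].shape[0]) - 1
        st = SimState(sites.shape[0], sites.shape[1], n_cells)
        st.sites = sites.copy()
        for name in SimState.CELL_ARRAYS:
            setattr(st, name, data[name].copy())
        st.mcs = int(data["mcs"])
        sim = cls(st, adhesion, config, mechanism, persistence)
        sim.rng_state = data["rng_state"].copy()
        sim.counters = data["counters"].copy()
        sim.persistence_active = bool(data["persistence_active"])
        sim.py_rng.bit_generator.state = json.loads(
            data["py_rng_state"].tobytes().decode())
        return sim


def run_simulation(state: SimState, adhesion: AdhesionTable,
                   config: SimConfig, mechanism: Mechanism = None,
                   persistence: Persistence | None = None,
                   record: bool = True) -> RunResult:
    """Convenience wrapper: build a :class:`Simulation` and run the full
    protocol."""
    return Simulation(state, adhesion, config, mechanism,
                      persistence).run(record=record)
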