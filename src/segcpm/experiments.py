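"""Experiment orchestration: named parameter presets, replicate runs and
on-disk run directories.

The package is driven from Python; an :class:`Experiment` bundles everything
a run needs (tissue geometry, adhesion table, optional mechanism/persistence,
run configuration) and :func:`run_experiment` executes one or more seeded
replicates, optionally writing a run directory with centroid tracks, the
tissue-shape series, snapshot images and a JSON manifest that reproduces the
run bitwise.

Presets cover the published experiment families: the explicit graded/axial
mechanisms with or without segment-specific adhesion, the pure
segment-adhesion tension grid, persistence ladders in small/large/stiff
tissues, the blocked-anterior variant and the opposing-gradient tissues.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .adhesion import Mechanism
from .engine import RunResult, Simulation
from .errors import ConfigurationError
from .geometry import TissueSpec, build_tissue, suggest_field
from .params import (AdhesionTable, AxialAdhesion, GradedAdhesion,
                     GradientAdhesion, Persistence, SimConfig)

__all__ = ["Experiment", "run_experiment", "preset", "PRESETS", "desk_scale"]


@dataclass
class Experiment:
    """A fully specified, reproducible simulation experiment."""

    name: str
    tissue: TissueSpec
    adhesion: AdhesionTable
    sim: SimConfig
    mechanism: Mechanism = None
    persistence: Persistence | None = None
    field_size: tuple[int, int] | None = None
    expected_fold: float = 2.0

    def __post_init__(self) -> None:
        n_mech = sum(isinstance(self.mechanism, t) for t in
                     (GradedAdhesion, AxialAdhesion, GradientAdhesion))
        if self.mechanism is not None and n_mech != 1:
            raise ConfigurationError(
                f"unknown mechanism object: {self.mechanism!r}")
        if isinstance(self.mechanism, GradientAdhesion) \
                and self.tissue.pattern == "segments":
            raise ConfigurationError(
                "the opposing-gradient mechanism needs a gradient tissue")

    def resolved_field(self) -> tuple[int, int]:
        if self.field_size is not None:
            return self.field_size
        return suggest_field(self.tissue, expected_fold=self.expected_fold)

    def build(self, seed: int) -> Simulation:
        """Construct the initial state and a ready-to-run simulation."""
        cfg = dataclasses.replace(self.sim, seed=int(seed))
        init_rng = np.random.default_rng(
            np.random.SeedSequence(int(seed)).spawn(1)[0])
        state = build_tissue(self.tissue, self.resolved_field(), rng=init_rng)
        return Simulation(state, self.adhesion, cfg,
                          mechanism=self.mechanism,
                          persistence=self.persistence)

    def to_manifest(self, seed: int) -> dict:
        def enc(obj):
            if obj is None:
                return None
            d = dataclasses.asdict(obj)
            d["__type__"] = type(obj).__name__
            return d

        manifest = {
            "name": self.name,
            "seed": int(seed),
            "tissue": enc(self.tissue),
            "adhesion_J": self.adhesion.matrix.tolist(),
            "sim": enc(self.sim),
            "mechanism": enc(self.mechanism),
            "persistence": enc(self.persistence),
            "field_size": list(self.resolved_field()),
        }
        blob = json.dumps(manifest, sort_keys=True).encode()
        manifest["config_hash"] = hashlib.sha256(blob).hexdigest()
        return manifest


def run_experiment(experiment: Experiment, seeds: int | list[int] = 1,
                   outdir: str | Path | None = None,
                   record: bool = True) -> list[RunResult]:
    """Run one replicate per seed and optionally persist a run directory.

    ``seeds`` is either a replicate count (seeds 0..k-1) or an explicit list.
    Each replicate writes ``tracks.csv``, ``shapes.csv``, ``manifest.json``
    and a final-state snapshot under ``<outdir>/<name>/seed<seed>/``.
    """
    if isinstance(seeds, int):
        seeds = list(range(seeds))
    results = []
    for seed in seeds:
        sim = experiment.build(seed)
        result = sim.run(record=record)
        results.append(result)
        if outdir is not None:
            rep_dir = Path(outdir) / experiment.name / f"seed{seed}"
            rep_dir.mkdir(parents=True, exist_ok=True)
            result.tracks.to_csv(rep_dir / "tracks.csv", index=False)
            result.shapes.to_csv(rep_dir / "shapes.csv", index=False)
            manifest = experiment.to_manifest(seed)
            manifest["final_mcs"] = int(result.state.mcs)
            manifest["counters"] = result.counters
            (rep_dir / "manifest.json").write_text(
                json.dumps(manifest, indent=2))
            from .render import render_snapshot
            render_snapshot(result.state, path=rep_dir / "final_state.png")
    return results


def desk_scale(experiment: Experiment, target_area: int = 100,
               duration: int | None = None) -> Experiment:
    """Shrink an experiment for interactive use: smaller cells and a shorter
    run.  Equilibrium tissue shape depends on tensions and segment geometry,
    not on cell size, so shape ratios are preserved; absolute lengths and
    time scales are not."""
    tissue = dataclasses.replace(experiment.tissue,
                                 cell_target_area=target_area)
    if duration is None:
        duration = max(experiment.sim.duration // 4, 10_000)
    init_period = min(experiment.sim.init_period, duration // 5)
    sim = dataclasses.replace(experiment.sim, duration=duration,
                              init_period=init_period)
    return dataclasses.replace(experiment, tissue=tissue, sim=sim,
                               name=experiment.name + "_desk")


# ---------------------------------------------------------------------------
# presets

def _segmented_experiment(name: str, *, J_cm: float, J_rr: float, J_rg: float,
                          n_segments: int = 4, rows: int = 3, cols: int = 10,
                          target_area: int = 500, duration: int = 500_000,
                          mechanism: Mechanism = None,
                          persistence: Persistence | None = None,
                          layout: str = "free",
                          expected_fold: float = 2.0) -> Experiment:
    return Experiment(
        name=name,
        tissue=TissueSpec(n_segments=n_segments, segment_rows=rows,
                          segment_cols=cols, cell_target_area=target_area,
                          layout=layout),
        adhesion=AdhesionTable.segmented(J_cm=J_cm, J_rr=J_rr, J_rg=J_rg),
        # persistence activates only after the seed blocks have inflated to
        # their target area; biasing a still-loose tissue shreds it
        sim=SimConfig(duration=duration,
                      init_period=5000 if persistence else 500),
        mechanism=mechanism,
        persistence=persistence,
        expected_fold=expected_fold,
    )


def _gradient_experiment(name: str, *, mm: float = 18.0, J_cm: float = 15.0,
                         J_max: float = 28.0, sorted_pattern: bool = True,
                         rows: int = 12, cols: int = 10,
                         target_area: int = 200, duration: int = 2_000_000,
                         persistence: Persistence | None = None) -> Experiment:
    pattern = "gradient_sorted" if sorted_pattern else "gradient_random"
    return Experiment(
        name=name,
        tissue=TissueSpec(n_segments=1, segment_rows=rows, segment_cols=cols,
                          cell_target_area=target_area, pattern=pattern),
        adhesion=AdhesionTable.gradient_tissue(J_cm=J_cm, J_max=J_max),
        sim=SimConfig(duration=duration,
                      init_period=5000 if persistence else 500),
        mechanism=GradientAdhesion(mm=mm),
        persistence=persistence,
        expected_fold=1.8,
    )


PRESETS: dict = {
    # explicit mechanisms, with/without segment-specific adhesion
    "graded_uniform": lambda: _segmented_experiment(
        "graded_uniform", J_cm=10, J_rr=16, J_rg=16,
        mechanism=GradedAdhesion(w=11, c=7)),
    "graded_segment_adhesion": lambda: _segmented_experiment(
        "graded_segment_adhesion", J_cm=10, J_rr=12, J_rg=16,
        mechanism=GradedAdhesion(w=11, c=7)),
    "axial_uniform": lambda: _segmented_experiment(
        "axial_uniform", J_cm=10, J_rr=16, J_rg=16,
        mechanism=AxialAdhesion(beta=2.0)),
    "axial_segment_adhesion": lambda: _segmented_experiment(
        "axial_segment_adhesion", J_cm=10, J_rr=12, J_rg=16,
        mechanism=AxialAdhesion(beta=2.0)),
    # segment-specific adhesion alone (tension grid maximum: gamma_rg=10,
    # gamma_cm=6)
    "segment_adhesion_gmax": lambda: _segmented_experiment(
        "segment_adhesion_gmax", J_cm=10, J_rr=8, J_rg=18,
        duration=1_000_000, expected_fold=2.2),
    "segment_adhesion_gmax_8seg": lambda: _segmented_experiment(
        "segment_adhesion_gmax_8seg", J_cm=10, J_rr=8, J_rg=18,
        n_segments=8, rows=2, cols=15, duration=1_000_000,
        expected_fold=3.0),
    "segment_adhesion_low": lambda: _segmented_experiment(
        "segment_adhesion_low", J_cm=10, J_rr=12, J_rg=16,
        duration=1_000_000),
    "no_mechanism_uniform": lambda: _segmented_experiment(
        "no_mechanism_uniform", J_cm=10, J_rr=16, J_rg=16),
    # persistence ladders (small / large / stiff); persistence runs use the
    # smaller cell size
    "persistence_uniform": lambda: _segmented_experiment(
        "persistence_uniform", J_cm=12, J_rr=18, J_rg=18, target_area=200,
        persistence=Persistence(mu=2.0, s=10), expected_fold=1.5),
    "persistence_small": lambda: _segmented_experiment(
        "persistence_small", J_cm=12, J_rr=16, J_rg=22, rows=2, cols=10,
        target_area=200, persistence=Persistence(mu=2.0, s=10)),
    "persistence_large": lambda: _segmented_experiment(
        "persistence_large", J_cm=12, J_rr=16, J_rg=22, rows=4, cols=20,
        target_area=200, persistence=Persistence(mu=1.0, s=10)),
    "stiff_large": lambda: _segmented_experiment(
        "stiff_large", J_cm=24, J_rr=32, J_rg=44, rows=4, cols=20,
        target_area=200, expected_fold=1.8),
    "stiff_large_persistence": lambda: _segmented_experiment(
        "stiff_large_persistence", J_cm=24, J_rr=32, J_rg=44, rows=4,
        cols=20, target_area=200, persistence=Persistence(mu=2.5, s=20),
        expected_fold=2.0),
    # constrained anterior end
    "blocked_anterior_gmax": lambda: _segmented_experiment(
        "blocked_anterior_gmax", J_cm=10, J_rr=8, J_rg=18,
        duration=1_000_000, layout="anterior_blocked", expected_fold=2.2),
    # opposing adhesion-protein gradients
    "gradient_sorted": lambda: _gradient_experiment(
        "gradient_sorted", sorted_pattern=True,
        persistence=Persistence(mu=0.5, s=5)),
    "gradient_random_sorting": lambda: _gradient_experiment(
        "gradient_random_sorting", sorted_pattern=False,
        persistence=Persistence(mu=2.0, s=30)),
    "gradient_random_no_persistence": lambda: _gradient_experiment(
        "gradient_random_no_persistence", sorted_pattern=False),
}


def preset(name: str, **overrides) -> Experiment:
    """Instantiate a named preset, optionally replacing dataclass fields
    (e.g. ``preset('segment_adhesion_gmax', sim=SimConfig(duration=10_000))``).
    """
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    exp = PRESETS[name]()
    if overrides:
        exp = dataclasses.replace(exp, **overrides)
    return exp
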