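"""Synthetic resting-state EEG cohorts with known network ground truth.

The generator emulates multichannel resting-state recordings in which the
functional network is controlled: per frequency band, a set of cortical
sources carries a narrow-band oscillation whose instantaneous phase obeys
Kuramoto dynamics on a Watts-Strogatz graph.  Each undirected edge is
given a random direction; the receiving oscillator is pulled toward the
driver's phase minus a fixed nonzero offset, so coupled pairs phase-lock
with a consistent *lagged* phase relation - exactly the kind of
interaction a phase-lag-sensitive connectivity estimator detects, and the
kind a zero-lag (volume-conduction) mixture does not produce.

Sources are superposed on 1/f background noise, optionally passed through
a zero-lag channel mixing matrix (volume conduction), and optionally
contaminated with mains-frequency sinusoids.  An experimental-condition
effect is injected by swapping in a different topology specification for
selected (condition, band) cells - by default, the theta-band graph is
fully randomized at the exhaustion condition while every other cell keeps
a small-world graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import networkx as nx
import numpy as np

from .bands import Band
from .containers import Recording
from .montage import DEFAULT_REFERENCE, default_montage

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

CONDITIONS = ("PRE", "ACUTE1", "ACUTE2", "ACUTE3", "REG1", "REG2")
EXHAUSTION_CONDITION = "ACUTE3"

# Default injected effect at the exhaustion condition: the theta-band
# source network is fully randomized AND its coupling gain is reduced.
# Randomization alone changes the graph's shape but (random graphs being
# more synchronizable) not the overall strength of measurable phase
# locking; the joint effect models a disorganized, weakened theta network
# and reproduces the empirically observed signature - lower clustering,
# lower small-world index - at the sensor level.
EXHAUSTION_REWIRING = 1.0
EXHAUSTION_COUPLING_FACTOR = 1.0 / 6.0


# --------------------------------------------------------------------------
# specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologySpec:
    """Ground-truth coupling graph for one frequency band.

    ``n_nodes`` sources sit on a ring lattice of even degree ``k``; each
    lattice edge is rewired with probability ``rewiring_prob``
    (Watts-Strogatz).  ``rewiring_prob`` near 0 yields a small-world
    graph, 1.0 a random graph with the same edge count.  Present edges
    couple phases with gain ``coupling_strength`` (rad/s) at a locked
    phase offset ``phase_offset`` (rad); the offset must not be 0 or pi,
    which would make the interaction invisible to lag-based estimators.
    """

    n_nodes: int
    k: int = 4
    rewiring_prob: float = 0.1
    coupling_strength: float = 3.0
    band: Band = Band("theta", 4.0, 8.0)
    phase_offset: float = math.pi / 4
    phase_noise: float = 0.7          # rad / sqrt(s), phase diffusion
    amplitude_uV: float = 5.0         # oscillation amplitude per source
    freq_jitter_hz: float = 0.2       # per-source natural-frequency spread

    def validate(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if self.k % 2 != 0 or not 0 < self.k < self.n_nodes:
            raise ValueError("k must be even and 0 < k < n_nodes")
        if not 0.0 <= self.rewiring_prob <= 1.0:
            raise ValueError("rewiring_prob must lie in [0, 1]")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")
        if abs(math.sin(self.phase_offset)) < 1e-9:
            raise ValueError("phase_offset of 0 or pi is invisible to lag estimators")


def _default_band_specs(n_sources: int) -> dict[str, TopologySpec]:
    return {
        "theta": TopologySpec(n_sources, band=Band("theta", 4.0, 8.0)),
        "alpha1": TopologySpec(n_sources, band=Band("alpha1", 8.0, 10.5)),
        "alpha2": TopologySpec(n_sources, band=Band("alpha2", 10.5, 13.0)),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full description of one synthetic cohort.

    Defaults mirror the emulated study: 16 subjects, six conditions
    (baseline, three acute post-exercise stages, two recovery stages),
    5-minute recordings at 500 Hz from a 65-electrode montage (64 data
    channels online-referenced to FCz).  The condition effect defaults to
    full randomization of the theta-band graph at ACUTE3.
    """

    n_subjects: int = 16
    conditions: tuple[str, ...] = CONDITIONS
    duration_s: float = 300.0
    fs: float = 500.0
    n_channels: int = 65              # montage size including the reference
    band_specs: Mapping[str, TopologySpec] | None = None
    condition_overrides: Mapping[str, Mapping[str, TopologySpec]] | None = None
    noise_exponent: float = 1.0       # 1/f^exponent background
    noise_amp_uV: float = 10.0        # RMS of the 1/f background per source
    sensor_noise_uV: float = 1.0      # white noise added per channel
    subject_freq_sd_hz: float = 0.15  # subject-level band-frequency shift
    subject_noise_sd_log: float = 0.15  # subject-level log noise-amplitude SD
    line_noise_freqs: tuple[float, ...] = ()
    line_noise_amp_uV: float = 0.0
    mixing: np.ndarray | None = None  # channels x sources zero-lag leakage
    seed: int = 0

    @property
    def n_data_channels(self) -> int:
        return self.n_channels - 1    # reference electrode carries no row

    @property
    def n_sources(self) -> int:
        if self.mixing is not None:
            return int(np.asarray(self.mixing).shape[1])
        return self.n_data_channels

    @property
    def n_samples(self) -> int:
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be an integer sample count")
        return int(round(n))

    def resolved_band_specs(self) -> dict[str, TopologySpec]:
        specs = (
            dict(self.band_specs)
            if self.band_specs is not None
            else _default_band_specs(self.n_sources)
        )
        for name, ts in specs.items():
            if ts.n_nodes != self.n_sources:
                raise ValueError(
                    f"band {name}: topology has {ts.n_nodes} nodes, "
                    f"cohort has {self.n_sources} sources"
                )
            ts.validate()
        return specs

    def resolved_overrides(self) -> dict[str, dict[str, TopologySpec]]:
        if self.condition_overrides is not None:
            out = {c: dict(m) for c, m in self.condition_overrides.items()}
        else:
            base = self.resolved_band_specs()
            out = {}
            if EXHAUSTION_CONDITION in self.conditions and "theta" in base:
                theta = base["theta"]
                out = {
                    EXHAUSTION_CONDITION: {
                        "theta": replace(
                            theta,
                            rewiring_prob=EXHAUSTION_REWIRING,
                            coupling_strength=(theta.coupling_strength
                                               * EXHAUSTION_COUPLING_FACTOR),
                        )
                    }
                }
        for cond, m in out.items():
            if cond not in self.conditions:
                raise ValueError(f"override for unknown condition {cond!r}")
            for ts in m.values():
                ts.validate()
        return out

    def cell_band_specs(self, condition: str) -> dict[str, TopologySpec]:
        """Band -> topology spec effective at one condition."""
        specs = self.resolved_band_specs()
        specs.update(self.resolved_overrides().get(condition, {}))
        return specs

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        if self.n_channels < 3:
            raise ValueError("need at least 3 channels")
        _ = self.n_samples
        if self.mixing is not None:
            m = np.asarray(self.mixing)
            if m.shape[0] != self.n_data_channels:
                raise ValueError("mixing must have one row per data channel")
        self.resolved_band_specs()
        self.resolved_overrides()


# --------------------------------------------------------------------------
# topology
# --------------------------------------------------------------------------

def make_topology(spec: TopologySpec, seed: int) -> np.ndarray:
    """Weighted adjacency matrix of one Watts-Strogatz realization.

    Symmetric, zero diagonal, exactly ``n_nodes * k / 2`` edges with
    weight ``coupling_strength``; deterministic in ``seed``.
    """
    spec.validate()
    g = nx.watts_strogatz_graph(spec.n_nodes, spec.k, spec.rewiring_prob,
                                seed=int(seed))
    adj = np.zeros((spec.n_nodes, spec.n_nodes))
    for u, v in g.edges():
        adj[u, v] = adj[v, u] = spec.coupling_strength
    return adj


# --------------------------------------------------------------------------
# phase dynamics
# --------------------------------------------------------------------------

def _integrate_phases_py(theta0, omega, coupling, phase_offset, dt, noise):
    n_steps, n = noise.shape
    out = np.empty((n_steps, n))
    theta = theta0.copy()
    for t in range(n_steps):
        out[t] = theta
        pull = np.zeros(n)
        for i in range(n):
            acc = 0.0
            for j in range(n):
                c = coupling[i, j]
                if c != 0.0:
                    acc += c * math.sin(theta[j] - theta[i] - phase_offset)
            pull[i] = acc
        theta = theta + dt * (omega + pull) + noise[t]
    return out


if _HAVE_NUMBA:
    _integrate_phases = njit(cache=True)(_integrate_phases_py)
else:  # pragma: no cover
    _integrate_phases = _integrate_phases_py


def _pink_noise(n_samples: int, exponent: float, rng: np.random.Generator,
                shape: tuple[int, ...] = ()) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise along the last axis."""
    white = rng.standard_normal(shape + (n_samples,))
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n_samples, axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x / rms


def _orient_edges(adj: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Assign each undirected edge a random direction.

    Returns a coupling matrix C where C[i, j] = w means source j drives
    source i; the receiver locks at the driver's phase minus the offset.
    """
    n = adj.shape[0]
    coupling = np.zeros_like(adj)
    iu, ju = np.triu_indices(n, k=1)
    present = adj[iu, ju] != 0.0
    iu, ju = iu[present], ju[present]
    forward = rng.random(iu.size) < 0.5
    w = adj[iu, ju]
    coupling[np.where(forward, iu, ju), np.where(forward, ju, iu)] = w
    return coupling


# --------------------------------------------------------------------------
# recording synthesis
# --------------------------------------------------------------------------

def synthesize_recording(
    spec: CohortSpec,
    topologies: Mapping[str, np.ndarray],
    seed: int | np.random.SeedSequence,
    subject_id: str = "S01",
    condition: str = "PRE",
    band_specs: Mapping[str, TopologySpec] | None = None,
    subject_effects: Mapping[str, float] | None = None,
) -> Recording:
    """Synthesize one subject-by-condition recording.

    ``topologies`` maps band name to a source adjacency matrix (as from
    :func:`make_topology`).  ``subject_effects`` optionally carries
    subject random effects (``freq_shift_<band>`` in Hz and
    ``noise_scale``); absent entries default to zero shift / unit scale.
    """
    spec.validate()
    band_specs = dict(band_specs) if band_specs is not None else spec.cell_band_specs(condition)
    if set(topologies) != set(band_specs):
        raise ValueError("topologies and band specs must cover the same bands")
    effects = dict(subject_effects or {})

    rng = np.random.default_rng(seed)
    n_samples = spec.n_samples
    n_sources = spec.n_sources
    dt = 1.0 / spec.fs
    t = np.arange(n_samples) * dt

    sources = np.zeros((n_sources, n_samples))
    for name in sorted(band_specs):
        ts = band_specs[name]
        adj = np.asarray(topologies[name], dtype=np.float64)
        if adj.shape != (n_sources, n_sources):
            raise ValueError(f"band {name}: adjacency shape {adj.shape} mismatch")
        f0 = ts.band.center + effects.get(f"freq_shift_{name}", 0.0)
        freqs = f0 + ts.freq_jitter_hz * rng.standard_normal(n_sources)
        omega = 2.0 * math.pi * freqs
        coupling = _orient_edges(adj, rng)
        theta0 = rng.uniform(0.0, 2.0 * math.pi, n_sources)
        noise = (ts.phase_noise * math.sqrt(dt)) * rng.standard_normal(
            (n_samples, n_sources)
        )
        phases = _integrate_phases(theta0, omega, coupling,
                                   ts.phase_offset, dt, noise)
        sources += ts.amplitude_uV * np.sin(phases.T)

    noise_amp = spec.noise_amp_uV * effects.get("noise_scale", 1.0)
    if noise_amp > 0:
        sources = sources + noise_amp * _pink_noise(
            n_samples, spec.noise_exponent, rng, (n_sources,)
        )

    if spec.mixing is not None:
        data = np.asarray(spec.mixing, dtype=np.float64) @ sources
    else:
        data = sources

    if spec.sensor_noise_uV > 0:
        data = data + spec.sensor_noise_uV * rng.standard_normal(data.shape)

    if spec.line_noise_freqs and spec.line_noise_amp_uV > 0:
        for f in spec.line_noise_freqs:
            phase = rng.uniform(0, 2 * math.pi)
            gains = 1.0 + 0.2 * rng.standard_normal(data.shape[0])
            data = data + spec.line_noise_amp_uV * gains[:, None] * np.sin(
                2 * math.pi * f * t + phase
            )

    if not np.all(np.isfinite(data)):
        raise FloatingPointError("synthesis produced non-finite samples")

    names = [c for c in default_montage(spec.n_channels) if c != DEFAULT_REFERENCE]
    return Recording(
        data=data,
        fs=spec.fs,
        channel_names=names,
        reference=DEFAULT_REFERENCE,
        subject_id=subject_id,
        condition=condition,
        meta={
            "generator": "rsnet.synthetic",
            "bands": {n: (band_specs[n].band.low, band_specs[n].band.high)
                      for n in band_specs},
        },
    )


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

@dataclass
class Cohort:
    """Synthetic cohort: recordings plus exported ground truth."""

    spec: CohortSpec
    recordings: dict[tuple[str, str], Recording]
    topologies: dict[tuple[str, str, str], np.ndarray]  # (subject, condition, band)

    @property
    def subjects(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.spec.n_subjects)]

    def __len__(self) -> int:
        return len(self.recordings)


def _subject_effects(spec: CohortSpec, subj_idx: int,
                     band_names: list[str]) -> dict[str, float]:
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, subj_idx))
    rng = np.random.default_rng(ss)
    eff: dict[str, float] = {
        "noise_scale": float(np.exp(spec.subject_noise_sd_log * rng.standard_normal()))
    }
    for name in sorted(band_names):
        eff[f"freq_shift_{name}"] = float(
            spec.subject_freq_sd_hz * rng.standard_normal()
        )
    return eff


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate all subject-by-condition recordings of a cohort.

    The whole cohort is a pure function of ``spec`` (including its seed).
    Seeds are derived per subject and condition from independent spawn
    keys, so enlarging the cohort leaves existing cells untouched.
    """
    spec.validate()
    recordings: dict[tuple[str, str], Recording] = {}
    topologies: dict[tuple[str, str, str], np.ndarray] = {}
    band_names = list(spec.resolved_band_specs())

    for si in range(spec.n_subjects):
        subject = f"S{si + 1:02d}"
        effects = _subject_effects(spec, si, band_names)
        for ci, condition in enumerate(spec.conditions):
            cell_specs = spec.cell_band_specs(condition)
            topo: dict[str, np.ndarray] = {}
            for bi, name in enumerate(sorted(cell_specs)):
                topo_seed = np.random.SeedSequence(
                    entropy=spec.seed, spawn_key=(2, si, ci, bi)
                ).generate_state(1)[0]
                topo[name] = make_topology(cell_specs[name], int(topo_seed))
                topologies[(subject, condition, name)] = topo[name]
            rec_seed = np.random.SeedSequence(entropy=spec.seed,
                                              spawn_key=(3, si, ci))
            recordings[(subject, condition)] = synthesize_recording(
                spec, topo, rec_seed, subject_id=subject, condition=condition,
                band_specs=cell_specs, subject_effects=effects,
            )
    return Cohort(spec=spec, recordings=recordings, topologies=topologies)
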