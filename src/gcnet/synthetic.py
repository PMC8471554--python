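"""Synthetic GC maps and VAR time series with planted causal-hub structure.

Patient iEEG recordings are not public, so this module generates surrogate
data whose statistical shape matches what the pipeline expects downstream of
the F-test pruning stage: sparse nonnegative directed weight matrices in
which a planted subset of nodes ("causal hubs", the ground-truth seizure
onset zone) has both a higher probability of emitting an edge and heavier
edge weights than the background. The hub/background contrast is a single
effect-size knob, ``hub_out_multiplier``.

Defaults mirror the study conditions: 100 nodes per patient (cohort mean
102.56 electrodes), 20 planted hubs (mean SOZ size 19.62), 60 segment maps
per patient, and a resection-zone label set derived from the hubs with a few
nodes dropped and added so RZ != SOZ with a slightly larger RZ (mean RZ size
21.88). Edge weights are exponential: GC magnitudes are nonnegative and
right-skewed; that distributional choice is a modelling convenience, not a
claim about real GC maps.

For end-to-end tests of the Granger stage, :func:`gen_var_segment` simulates
a stable VAR process whose coefficient matrix encodes a planted directed
edge set, so the pipeline's ability to recover known causal structure can be
measured from raw time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gcmap import GCMap, PatientRecord
from .granger import Segment

__all__ = ["SynthConfig", "gen_patient", "gen_var_segment"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic patient.

    ``edge_density`` is the background probability of each directed edge;
    planted hubs emit edges with probability ``edge_density *
    hub_out_multiplier`` (which must stay <= 1) and their edge weights have
    mean ``weight_scale * hub_out_multiplier`` instead of ``weight_scale``.
    ``rz_drop``/``rz_add`` hubs are removed from / background nodes added to
    the hub set to form the resection zone.
    """

    n_nodes: int = 100
    n_soz: int = 20
    edge_density: float = 0.1
    hub_out_multiplier: float = 3.0
    weight_scale: float = 1.0
    n_segments: int = 60
    rz_drop: int = 2
    rz_add: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.edge_density <= 1):
            raise ValueError("edge_density must be in (0, 1]")
        if self.hub_out_multiplier < 1:
            raise ValueError("hub_out_multiplier must be >= 1")
        if self.edge_density * self.hub_out_multiplier > 1 + 1e-12:
            raise ValueError("edge_density * hub_out_multiplier must be <= 1")
        if not (0 < self.n_soz < self.n_nodes):
            raise ValueError("need 0 < n_soz < n_nodes")
        if self.n_segments < 1 or self.weight_scale <= 0:
            raise ValueError("n_segments >= 1 and weight_scale > 0 required")
        if self.rz_drop > self.n_soz or self.rz_add > self.n_nodes - self.n_soz:
            raise ValueError("rz perturbation exceeds available nodes")


def gen_patient(cfg: SynthConfig) -> tuple[PatientRecord, set[str]]:
    """Generate one synthetic patient; returns (record, planted hub labels).

    The record's SOZ is exactly the planted hub set; the RZ is the hub set
    with ``rz_drop`` hubs removed and ``rz_add`` background nodes added.
    Bit-identical output for identical config (seed included).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nodes
    labels = [f"n{i}" for i in range(n)]
    hubs = np.sort(rng.choice(n, size=cfg.n_soz, replace=False))
    hub_set = {labels[i] for i in hubs}

    edge_prob = np.full(n, cfg.edge_density)
    edge_prob[hubs] = min(cfg.edge_density * cfg.hub_out_multiplier, 1.0)
    w_scale = np.full(n, cfg.weight_scale)
    w_scale[hubs] = cfg.weight_scale * cfg.hub_out_multiplier

    # RZ perturbation drawn before the segment stream so segment draws are
    # unaffected by rz_drop/rz_add settings
    keep = rng.choice(hubs, size=cfg.n_soz - cfg.rz_drop, replace=False)
    background = np.setdiff1d(np.arange(n), hubs)
    extra = rng.choice(background, size=cfg.rz_add, replace=False)
    rz = {labels[i] for i in keep} | {labels[i] for i in extra}

    segments = []
    for _ in range(cfg.n_segments):
        present = rng.random((n, n)) < edge_prob[:, None]
        np.fill_diagonal(present, False)
        w = rng.exponential(scale=w_scale[:, None], size=(n, n))
        segments.append(GCMap(np.where(present, w, 0.0), labels))
    return PatientRecord(segments, hub_set, rz), hub_set


def _companion_radius(coeffs: np.ndarray) -> float:
    p, c, _ = coeffs.shape
    comp = np.zeros((p * c, p * c))
    comp[:c] = np.hstack(list(coeffs))
    if p > 1:
        comp[c:, : (p - 1) * c] = np.eye((p - 1) * c)
    return float(np.abs(np.linalg.eigvals(comp)).max())


def gen_var_segment(
    n_channels: int,
    planted_edges: set[tuple[int, int]],
    coupling: float = 0.5,
    T: int = 4000,
    order: int = 1,
    seed: int = 0,
    *,
    self_decay: float = 0.5,
    sample_rate: float = 500.0,
    burn_in: int = 200,
) -> tuple[Segment, set[tuple[int, int]]]:
    """Simulate a stable VAR(order) with planted directed lag-1 couplings.

    Each channel decays toward zero with coefficient ``self_decay`` on its own
    first lag; each planted edge (i, j) adds coefficient ``coupling`` from
    channel i's first lag into channel j. Innovations are independent unit
    Gaussians. If the companion matrix is unstable the coefficients are
    rescaled (with a warning-free deterministic shrink); a configuration that
    cannot be stabilised raises.
    """
    if n_channels < 2 or order < 1 or T <= 3 * order + 1:
        raise ValueError("need n_channels >= 2, order >= 1 and T > 3*order + 1")
    for i, j in planted_edges:
        if i == j or not (0 <= i < n_channels and 0 <= j < n_channels):
            raise ValueError(f"invalid planted edge {(i, j)}")
    coeffs = np.zeros((order, n_channels, n_channels))
    coeffs[0] += np.eye(n_channels) * self_decay
    for i, j in planted_edges:
        coeffs[0, j, i] = coupling  # row = equation (target), col = lagged source
    radius = _companion_radius(coeffs)
    if radius >= 0.98:
        scale = 0.95 / radius
        for lag in range(order):
            coeffs[lag] *= scale ** (lag + 1)
        radius = _companion_radius(coeffs)
        if radius >= 1.0:
            raise ValueError("VAR configuration could not be stabilised")

    rng = np.random.default_rng(seed)
    total = T + burn_in
    x = np.zeros((n_channels, total))
    eps = rng.standard_normal((n_channels, total))
    for t in range(order, total):
        acc = eps[:, t].copy()
        for lag in range(order):
            acc += coeffs[lag] @ x[:, t - lag - 1]
        x[:, t] = acc
    labels = [f"ch{i}" for i in range(n_channels)]
    return Segment(x[:, burn_in:], labels, sample_rate), set(planted_edges)
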