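"""Synthetic TMS-EEG cohorts with known ground truth.

This module manufactures every input the analysis pipeline consumes: a
toy head model (lead field, voxel -> ROI -> network lookups), per-group
ground-truth Ising parameters, binary network states sampled from their
Boltzmann distributions, and multi-trial scalp EEG in which those states
amplitude-modulate alpha-band (8-12 Hz) sources inside the target
network's ROIs.

Default cohort sizes follow the three-site study design: 22/27
patients/controls for left motor cortex stimulation, 9/18 for left
prefrontal, 12/25 for vermis, with about 60 trials per subject.  Epochs
are 2 s at 1000 Hz with the TMS pulse at mid-epoch, so decimation by 2
leaves the canonical 500-sample pre and post windows.

The scalp signal for each subject is trial-locked: a single clean source
time course is mixed through the lead field and repeated over trials with
fresh sensor noise (plus occasional injected high-amplitude artifacts),
which is exactly the signal-plus-noise decomposition that ERP averaging
assumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .landscape import MaxEntModel, boltzmann
from .networks import NetworkDefinition, all_regions, default_networks
from .preprocess import DEFAULT_CHANNELS, EpochSet

__all__ = [
    "SITE_LABELS",
    "DEFAULT_COHORT_SIZES",
    "CohortSpec",
    "GroundTruth",
    "ToyHeadModel",
    "SubjectData",
    "make_head_model",
    "make_ground_truth",
    "sample_ising_series",
    "synthesize_cohort",
    "iter_cohort",
]

SITE_LABELS = ("left_motor", "left_prefrontal", "vermis")

#: (patients, controls) per stimulation site
DEFAULT_COHORT_SIZES = {
    "left_motor": (22, 27),
    "left_prefrontal": (9, 18),
    "vermis": (12, 25),
}

#: target network whose activity each site's stimulation modulates
DEFAULT_TARGET_NETWORKS = {
    "left_motor": "sensorimotor",
    "left_prefrontal": "attention",
    "vermis": "frontoparietal",
}

# approximate extended 10-20 electrode positions on a unit sphere
# (x: left->right, y: back->front, z: up)
_ELECTRODE_XYZ = {
    "F3": (-0.55, 0.60, 0.58),
    "FZ": (0.00, 0.72, 0.70),
    "F4": (0.55, 0.60, 0.58),
    "T3": (-0.99, 0.00, 0.12),
    "CZ": (0.00, 0.00, 1.00),
    "T4": (0.99, 0.00, 0.12),
    "P3": (-0.55, -0.60, 0.58),
    "PZ": (0.00, -0.72, 0.70),
    "P4": (0.55, -0.60, 0.58),
    "O1": (-0.31, -0.95, 0.05),
    "O2": (0.31, -0.95, 0.05),
}


@dataclass(frozen=True)
class CohortSpec:
    """Sizes and identity of one stimulation-site cohort."""

    n_patients: int
    n_controls: int
    site_label: str
    n_trials_per_subject: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_label not in SITE_LABELS:
            raise ValueError(
                f"unknown site_label {self.site_label!r}; expected one of {SITE_LABELS}"
            )
        for name in ("n_patients", "n_controls", "n_trials_per_subject"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def for_site(cls, site_label: str, seed: int = 0, **kwargs) -> "CohortSpec":
        n_pat, n_con = DEFAULT_COHORT_SIZES[site_label]
        return cls(n_pat, n_con, site_label, seed=seed, **kwargs)

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    def subjects(self) -> list[tuple[str, str]]:
        """(subject_id, group) rows, patients first then controls."""
        rows = [
            (f"{self.site_label}-pat{i + 1:02d}", "patients")
            for i in range(self.n_patients)
        ]
        rows += [
            (f"{self.site_label}-con{i + 1:02d}", "controls")
            for i in range(self.n_controls)
        ]
        return rows


@dataclass
class GroundTruth:
    """Planted Ising parameters per (group, condition) for one network.

    ``models`` maps ('patients'|'controls', 'pre'|'post') to a
    :class:`MaxEntModel`; ``planted_effect`` records the coupling shift
    applied to the target cell so recovery tests can refer back to it.
    """

    network: NetworkDefinition
    models: dict[tuple[str, str], MaxEntModel]
    planted_effect: float = 0.0
    planted_cell: tuple[str, str] = ("patients", "post")

    def to_jsonable(self) -> dict:
        return {
            "network": self.network.name,
            "regions": list(self.network.regions),
            "planted_effect": self.planted_effect,
            "planted_cell": list(self.planted_cell),
            "models": {
                f"{g}/{c}": {"h": m.h.tolist(), "J": m.J.tolist()}
                for (g, c), m in self.models.items()
            },
        }


@dataclass
class ToyHeadModel:
    """Random-geometry lead field plus voxel/ROI/network lookup tables.

    ``K`` is (11, 3 N_V): three free-orientation dipole components per
    voxel, columns scaled so a unit dipole moment produces on the order of
    one microvolt at the scalp.
    """

    K: np.ndarray
    electrode_labels: tuple[str, ...]
    electrode_positions: np.ndarray
    voxel_positions: np.ndarray
    voxel_to_roi: tuple[str, ...]
    networks: dict[str, NetworkDefinition]

    @property
    def n_electrodes(self) -> int:
        return self.K.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.K.shape[1] // 3

    @property
    def roi_to_network(self) -> dict[str, tuple[str, ...]]:
        """ROI -> names of the networks that list it (may be several)."""
        table: dict[str, list[str]] = {}
        for net in self.networks.values():
            for roi in net.regions:
                table.setdefault(roi, []).append(net.name)
        return {roi: tuple(names) for roi, names in table.items()}

    def roi_voxels(self, roi: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.voxel_to_roi, dtype=object) == roi)
        if idx.size == 0:
            raise KeyError(f"ROI {roi!r} owns no voxels")
        return idx

    def to_jsonable(self) -> dict:
        return {
            "K": self.K.tolist(),
            "electrode_labels": list(self.electrode_labels),
            "electrode_positions": self.electrode_positions.tolist(),
            "voxel_positions": self.voxel_positions.tolist(),
            "voxel_to_roi": list(self.voxel_to_roi),
            "networks": {n: list(d.regions) for n, d in self.networks.items()},
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "ToyHeadModel":
        return cls(
            K=np.asarray(obj["K"], dtype=float),
            electrode_labels=tuple(obj["electrode_labels"]),
            electrode_positions=np.asarray(obj["electrode_positions"], dtype=float),
            voxel_positions=np.asarray(obj["voxel_positions"], dtype=float),
            voxel_to_roi=tuple(obj["voxel_to_roi"]),
            networks={
                n: NetworkDefinition(n, tuple(r)) for n, r in obj["networks"].items()
            },
        )


def make_head_model(
    n_voxels: int = 52,
    seed: int = 0,
    networks: dict[str, NetworkDefinition] | None = None,
) -> ToyHeadModel:
    """Build a reproducible random-geometry toy head model.

    Voxels are placed uniformly in a ball of radius 0.75 inside the unit
    electrode sphere and assigned to ROIs round-robin so every ROI in the
    network tables owns at least one voxel.  The forward model is the
    potential of a current dipole in an unbounded homogeneous conductor,
    which is linear and full row rank - sufficient for exercising the
    inverse stage without any claim of anatomical realism.
    """
    networks = dict(networks) if networks is not None else default_networks()
    rois = all_regions(networks)
    if n_voxels < len(rois):
        uncovered = rois[n_voxels:]
        raise ValueError(
            f"n_voxels={n_voxels} is too small to cover all {len(rois)} ROIs; "
            f"uncovered: {list(uncovered)}"
        )
    rng = np.random.default_rng([seed, 7001])
    directions = rng.normal(size=(n_voxels, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = 0.75 * rng.uniform(size=n_voxels) ** (1.0 / 3.0)
    voxel_positions = directions * radii[:, np.newaxis]
    voxel_to_roi = tuple(rois[v % len(rois)] for v in range(n_voxels))

    electrode_positions = np.array([_ELECTRODE_XYZ[ch] for ch in DEFAULT_CHANNELS])
    electrode_positions /= np.linalg.norm(electrode_positions, axis=1, keepdims=True)

    K = np.empty((len(DEFAULT_CHANNELS), 3 * n_voxels))
    for v in range(n_voxels):
        delta = electrode_positions - voxel_positions[v]
        K[:, 3 * v : 3 * v + 3] = delta / (
            4.0 * np.pi * np.linalg.norm(delta, axis=1, keepdims=True) ** 3
        )
    # normalize the overall gain so unit dipole moments land in the uV range
    block_gains = np.linalg.norm(
        K.reshape(len(DEFAULT_CHANNELS), n_voxels, 3), axis=(0, 2)
    )
    K /= np.median(block_gains)

    if np.linalg.matrix_rank(K) < len(DEFAULT_CHANNELS):
        raise np.linalg.LinAlgError("toy lead field is rank deficient; change the seed")
    return ToyHeadModel(
        K=K,
        electrode_labels=DEFAULT_CHANNELS,
        electrode_positions=electrode_positions,
        voxel_positions=voxel_positions,
        voxel_to_roi=voxel_to_roi,
        networks=networks,
    )


def make_ground_truth(
    network: NetworkDefinition,
    *,
    planted_effect: float = 0.0,
    seed: int = 0,
    h_scale: float = 0.3,
    j_scale: float = 0.15,
    planted_cell: tuple[str, str] = ("patients", "post"),
) -> GroundTruth:
    """Draw base (h, J) once and plant a coupling shift in one cell.

    All four (group, condition) cells share the same base parameters;
    ``planted_effect`` is added to every off-diagonal coupling of the
    ``planted_cell`` (patients post-TMS by default).  A zero effect makes
    the groups exchangeable, which null-calibration tests rely on.
    """
    m = network.n_regions
    rng = np.random.default_rng([seed, 101])
    h0 = rng.normal(0.0, h_scale, size=m)
    upper = rng.normal(0.0, j_scale, size=(m, m))
    J0 = np.triu(upper, k=1)
    J0 = J0 + J0.T
    models = {}
    for group in ("patients", "controls"):
        for condition in ("pre", "post"):
            J = J0.copy()
            if (group, condition) == planted_cell and planted_effect != 0.0:
                J = J + planted_effect * (1.0 - np.eye(m))
            models[(group, condition)] = MaxEntModel(h=h0.copy(), J=J)
    return GroundTruth(
        network=network,
        models=models,
        planted_effect=planted_effect,
        planted_cell=planted_cell,
    )


def sample_ising_series(model, n_samples: int, seed) -> np.ndarray:
    """Draw i.i.d. activity patterns from a model's Boltzmann distribution.

    ``model`` is a :class:`MaxEntModel` or an ``(h, J)`` pair; ``seed`` is
    anything :func:`numpy.random.default_rng` accepts, including an
    existing generator.  Returns an (n_samples, M) array of +-1.  Exact
    enumeration restricts M to at most 12.
    """
    if not isinstance(model, MaxEntModel):
        h, J = model
        model = MaxEntModel(h=h, J=J)
    m = model.n_regions
    probs = boltzmann(model)  # raises for M > 12
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = rng.choice(probs.size, size=n_samples, p=probs)
    return np.where((codes[:, None] >> np.arange(m)) & 1, 1.0, -1.0)


@dataclass
class SubjectData:
    """One synthetic subject: raw epochs plus the planted state sequences."""

    subject_id: str
    group: str
    site: str
    epochs: EpochSet
    states: dict[str, np.ndarray]


def _orthonormal_pair(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return q[:, 0], q[:, 1]


def _quadrature_axes(head: ToyHeadModel) -> np.ndarray:
    """Per-voxel dipole axes that give rotation-invariant standardized power.

    A rotating (quadrature) dipole has constant moment magnitude, but a
    rank-deficient inverse reconstructs its two axes with different gains,
    so the standardized power would ripple at twice the carrier frequency.
    Planting the two quadrature components along the top eigenvectors of
    the voxel's resolution block S_vv, scaled by 1/sqrt(eigenvalue),
    cancels that anisotropy exactly: the quadratic form j' S_vv^{-1} j of
    the reconstruction is then constant over the carrier cycle.  Returns
    an (n_voxels, 3, 2) array of paired axes.
    """
    K = head.K
    n_e = K.shape[0]
    H = np.eye(n_e) - np.full((n_e, n_e), 1.0 / n_e)
    Kc = H @ K
    w, V = np.linalg.eigh(Kc @ Kc.T)
    keep = w > 1e-10 * w.max()
    inv = V[:, keep] / w[keep] @ V[:, keep].T
    T = Kc.T @ inv
    t_blocks = T.reshape(head.n_voxels, 3, n_e)
    k_blocks = np.moveaxis(Kc.reshape(n_e, head.n_voxels, 3), 1, 0)
    S = np.einsum("vae,vef->vaf", t_blocks, k_blocks)
    axes = np.empty((head.n_voxels, 3, 2))
    for v in range(head.n_voxels):
        evals, evecs = np.linalg.eigh(S[v])
        pair = np.stack(
            [evecs[:, -1] / np.sqrt(evals[-1]), evecs[:, -2] / np.sqrt(evals[-2])],
            axis=1,
        )
        # common rescale to a unit mean-square dipole moment: keeps the
        # anisotropy cancellation while leaving amplitudes in source units
        pair *= np.sqrt(2.0 / np.sum(pair**2))
        axes[v] = pair
    return axes


def _simulate_subject(
    subject_id: str,
    group: str,
    spec: CohortSpec,
    truth: GroundTruth,
    head: ToyHeadModel,
    subject_index: int,
    *,
    fs_hz: float,
    epoch_samples: int,
    dwell_samples: int,
    a_active: float,
    a_inactive: float,
    a_background: float,
    noise_sigma_uv: float,
    artifact_fraction: float,
    artifact_uv: float,
    carrier_freqs: np.ndarray | None,
    voxel_phases: np.ndarray,
    background_freqs: np.ndarray,
) -> SubjectData:
    rng = np.random.default_rng(
        [spec.seed, SITE_LABELS.index(spec.site_label), subject_index]
    )
    half = epoch_samples // 2
    n_states = half // dwell_samples
    if n_states < 1:
        raise ValueError("dwell time longer than the pre/post window")
    regions = truth.network.regions
    m = len(regions)
    states = {
        cond: sample_ising_series(truth.models[(group, cond)], n_states, rng)
        for cond in ("pre", "post")
    }
    # per-region amplitude envelope over the full epoch (pre then post)
    envelopes = np.empty((m, epoch_samples))
    for r in range(m):
        for w, cond in enumerate(("pre", "post")):
            amp = np.where(states[cond][:, r] > 0, a_active, a_inactive)
            envelopes[r, w * half : (w + 1) * half] = np.repeat(amp, dwell_samples)

    # distinct alpha carrier frequency per region keeps sources incoherent
    if carrier_freqs is not None:
        region_freq = np.asarray(carrier_freqs, dtype=float)
    else:
        region_freq = np.linspace(8.8, 11.2, m) if m > 1 else np.array([10.0])
    # carrier time restarts at the pulse (TMS-locked alpha phase reset):
    # the pre and post windows then see identical carrier/dwell alignment,
    # so the two windows pass through the same effective mixing
    t = np.concatenate([np.arange(half), np.arange(epoch_samples - half)]) / fs_hz
    axes = getattr(head, "_quadrature_axes_cache", None)
    if axes is None:
        axes = _quadrature_axes(head)
        head._quadrature_axes_cache = axes
    sources = np.zeros((3 * head.n_voxels, epoch_samples))
    for v in range(head.n_voxels):
        roi = head.voxel_to_roi[v]
        if roi in regions:
            r = regions.index(roi)
            envelope, freq = envelopes[r], region_freq[r]
        else:
            envelope, freq = a_background, background_freqs[v]
        theta = 2.0 * np.pi * freq * t + voxel_phases[v]
        # quadrature pair along the voxel's balanced reconstruction axes:
        # a rotating dipole whose standardized power tracks the envelope
        # rather than the carrier phase
        sources[3 * v : 3 * v + 3] = envelope * (
            np.outer(axes[v, :, 0], np.cos(theta))
            + np.outer(axes[v, :, 1], np.sin(theta))
        )
    clean = head.K @ sources

    n_trials = spec.n_trials_per_subject
    data = np.empty((n_trials, clean.shape[0], epoch_samples))
    for k in range(n_trials):
        trial = clean + rng.normal(0.0, noise_sigma_uv, size=clean.shape)
        if rng.random() < artifact_fraction:
            ch = int(rng.integers(clean.shape[0]))
            start = int(rng.integers(0, epoch_samples - 100))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            trial[ch, start : start + 100] += sign * artifact_uv
        data[k] = trial
    epochs = EpochSet(
        data=data,
        fs_hz=fs_hz,
        pulse_sample=half,
        channel_labels=head.electrode_labels,
        subject_id=subject_id,
    )
    return SubjectData(
        subject_id=subject_id, group=group, site=spec.site_label, epochs=epochs, states=states
    )


def iter_cohort(
    spec: CohortSpec,
    truth: GroundTruth,
    head: ToyHeadModel,
    *,
    fs_hz: float = 1000.0,
    epoch_samples: int = 2000,
    dwell_ms: float = 100.0,
    a_active: float = 8.0,
    a_inactive: float = 1.0,
    a_background: float = 0.5,
    noise_sigma_uv: float = 2.0,
    artifact_fraction: float = 0.1,
    artifact_uv: float = 120.0,
    carrier_freqs: np.ndarray | None = None,
) -> Iterator[SubjectData]:
    """Yield synthetic subjects one at a time (memory-friendly).

    Each subject draws from an independent random substream keyed by
    (cohort seed, site, subject index), so enlarging the cohort leaves
    earlier subjects bit-identical.  Binary network states dwell for
    ``dwell_ms`` and modulate the amplitude (``a_active`` vs
    ``a_inactive``, in source units roughly equal to scalp microvolts) of
    alpha carriers in the target network's ROI voxels; all other voxels
    hum at ``a_background``.  A random ``artifact_fraction`` of trials
    receives a 100 ms, +-``artifact_uv`` square pulse on one channel to
    exercise the rejection stage.
    """
    dwell_samples = int(round(dwell_ms * fs_hz / 1000.0))
    # carrier phases and background frequencies are cohort-level constants:
    # every subject sees the same alpha "channel", so group contrasts are
    # not diluted by per-subject re-randomization of the lead-field mixing
    cohort_rng = np.random.default_rng(
        [spec.seed, SITE_LABELS.index(spec.site_label), 999]
    )
    voxel_phases = cohort_rng.uniform(0.0, 2.0 * np.pi, size=head.n_voxels)
    background_freqs = cohort_rng.uniform(8.0, 12.0, size=head.n_voxels)
    for index, (subject_id, group) in enumerate(spec.subjects()):
        yield _simulate_subject(
            subject_id,
            group,
            spec,
            truth,
            head,
            index,
            fs_hz=fs_hz,
            epoch_samples=epoch_samples,
            dwell_samples=dwell_samples,
            a_active=a_active,
            a_inactive=a_inactive,
            a_background=a_background,
            noise_sigma_uv=noise_sigma_uv,
            artifact_fraction=artifact_fraction,
            artifact_uv=artifact_uv,
            carrier_freqs=carrier_freqs,
            voxel_phases=voxel_phases,
            background_freqs=background_freqs,
        )


def synthesize_cohort(
    spec: CohortSpec, truth: GroundTruth, head: ToyHeadModel, **kwargs
) -> tuple[list[SubjectData], dict]:
    """Materialize a whole cohort plus a ground-truth sidecar.

    The sidecar records the cohort spec, planted models, and per-subject
    state sequences, and is what recovery tests compare against.  See
    :func:`iter_cohort` for the generation parameters.
    """
    subjects = list(iter_cohort(spec, truth, head, **kwargs))
    sidecar = {
        "spec": {
            "n_patients": spec.n_patients,
            "n_controls": spec.n_controls,
            "site_label": spec.site_label,
            "n_trials_per_subject": spec.n_trials_per_subject,
            "seed": spec.seed,
        },
        "ground_truth": truth.to_jsonable(),
        "subject_states": {
            s.subject_id: {cond: st.tolist() for cond, st in s.states.items()}
            for s in subjects
        },
    }
    return subjects, sidecar
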