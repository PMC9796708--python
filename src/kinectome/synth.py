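"""Synthetic motion-capture cohorts with controllable network structure.

The generator emulates the statistical properties that the downstream
analyses assume of real gait data, using a harmonic-template model rather
than a biomechanical simulation: every analysis in this package consumes
only the correlation structure of acceleration/jerk series, which sums of
gait-frequency harmonics with controlled phases reproduce transparently.

Each marker's trajectory along each axis is

    x(t) = offset + A * [ sqrt(l) * L(t) + sqrt(1-l) * P(t) ] + ...

where L is a module-shared latent waveform (sum of harmonics of the gait
frequency), P a marker-private waveform with the same spectrum, and l the
latent (coordination) share.  Module memberships and waveform profiles per
axis encode gait biomechanics: contralateral arm-leg antiphase along the
anteroposterior axis, a trunk/head/pelvis stabilization split mediolaterally,
and a double-bump whole-body vertical oscillation with arms and feet
distinct.  Subject identity (the "signature", stable across the two trials)
enters through seeded phase offsets, per-marker timing lags, and mixing
perturbations; per-trial variation enters through a global gait-phase shift,
small phase jitter, and additive noise band-limited to the gait harmonics
(marker trajectories are smooth, so broadband noise would be unphysical and
would dominate the second and third derivatives).

A subject-specific "axial rigidity drive" — a high-harmonic waveform
orthogonal to all module latents — is always present in the trunk anchor's
(T10) motion.  Disease mode ("parkinsonian") additionally (i) weakens the
left side's coordination share (asymmetry), (ii) couples the rigidity drive
into the distal ML/AP channels with a per-subject strength drawn around
``trunk_coupling`` (trunk-limb hypersynchronization centered on T10),
(iii) inflates between-subject variability along the anteroposterior axis,
(iv) raises within-trial variability (dysregulation), and (v) derives the
synthetic motor score linearly from the realized coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AXES, MarkerTrial
from .markers import MarkerSet, default_marker_set
from .network import EdgeVector, edge_index_pairs

__all__ = ["CohortSpec", "generate_cohort", "planted_truth",
           "planted_edge_cohort"]

# receivers of the disease-mode trunk coupling: distal segments only (the
# shoulder/elbow markers ride on the trunk and are not coupled separately)
_COUPLING_GROUPS = frozenset({"forearm", "leg", "foot"})

# Template module memberships per axis (marker indices in default order).
_TEMPLATE_COMMUNITIES: dict[str, tuple[tuple[int, ...], ...]] = {
    # trunk+upper arms | head+forearms+pelvis | legs+feet
    "ML": ((2, 3, 4, 5, 6, 7),
           (0, 1, 8, 9, 10, 11, 12),
           (13, 14, 15, 16, 17, 18, 19, 20)),
    # head+trunk+pelvis | left leg/foot + right arm | right leg/foot + left arm
    "AP": ((0, 1, 2, 3, 10, 11, 12),
           (4, 6, 8, 14, 16, 18, 20),
           (5, 7, 9, 13, 15, 17, 19)),
    # whole body minus arms/feet | arms | feet
    "V": ((0, 1, 2, 3, 10, 11, 12, 13, 14, 15, 16),
          (4, 5, 6, 7, 8, 9),
          (17, 18, 19, 20)),
}

# Per-axis module waveforms: harmonic weights and phases (3 harmonics).
# Profiles are chosen so that cross-module correlations are small while
# within-module correlations stay high (distinct dominant harmonics and
# quadrature phase offsets between modules).
_TEMPLATE_PROFILES: dict[str, dict[str, np.ndarray]] = {
    "ML": {
        "weights": np.array([[1.0, 0.3, 0.1],
                             [0.3, 1.0, 0.15],
                             [0.25, 0.2, 1.0]]),
        # legs/feet sit near quadrature to the trunk module (slightly past,
        # for a small positive baseline coupling) so that disease-mode
        # trunk-limb coupling adds coherently rather than cancelling
        "phases": np.array([[0.0, 0.0, 0.0],
                            [np.pi / 2] * 3,
                            [3 * np.pi / 2 + 0.25] * 3]),
    },
    "AP": {
        "weights": np.array([[0.3, 1.0, 0.15],
                             [1.0, 0.6, 0.15],
                             [1.0, 0.6, 0.15]]),
        "phases": np.array([[np.pi / 2] * 3,
                            [0.0, 0.0, 0.0],
                            [np.pi, np.pi / 2, 0.0]]),
    },
    "V": {
        "weights": np.array([[0.3, 1.0, 0.15],
                             [1.0, 0.3, 0.1],
                             [0.4, 0.3, 1.0]]),
        "phases": np.array([[np.pi / 2] * 3,
                            [0.0, 0.0, 0.0],
                            [np.pi] * 3]),
    },
}

# Base oscillation amplitudes (m) per anatomical group and axis.
_GROUP_AMPLITUDES: dict[str, tuple[float, float, float]] = {
    # (ML, AP, V)
    "head": (0.015, 0.020, 0.025),
    "trunk": (0.020, 0.025, 0.025),
    "upper_arm": (0.030, 0.050, 0.030),
    "forearm": (0.040, 0.080, 0.035),
    "pelvis": (0.025, 0.020, 0.030),
    "leg": (0.020, 0.060, 0.030),
    "foot": (0.025, 0.100, 0.050),
}

# Axial "rigidity drive": a high-harmonic waveform carried by the trunk
# anchor (T10) at a fixed share and by each distal channel at the
# per-subject coupling strength in disease mode.  Its phases are solved (per
# axis) to be orthogonal to all three module latents, so trunk-limb edges
# gain first-order coupling sensitivity while limb-limb edges gain only
# second order; the h^3-dominant spectrum keeps the coupled share visible
# after double/triple differentiation.  Shares are specified in
# acceleration units (the quantity the movement network measures) and
# converted to position scale per receiver, so a given coupling strength
# means the same thing for a wrist as for a heel despite their different
# harmonic content.
_RIGIDITY_WEIGHTS = np.array([0.3, 0.5, 1.0])
_RIGIDITY_PHASES: dict[str, np.ndarray] = {
    "ML": np.array([1.4116611355, 3.3749840919, 0.1794708718]),
    "AP": np.array([2.1251577213, 6.2288837846, 3.4770763148]),
    "V": np.array([1.0880858095, 3.0018672359, 4.8053591915]),
}
_RIGIDITY_T10_SHARE = 0.75  # acceleration-share of the drive in T10

# Static rest offsets (m): rough standing posture, vertical by group.
_GROUP_HEIGHTS: dict[str, float] = {
    "head": 1.65, "trunk": 1.30, "upper_arm": 1.20, "forearm": 0.85,
    "pelvis": 1.00, "leg": 0.35, "foot": 0.05,
}
_WALK_SPEED = 1.2  # m/s forward progression along AP


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Mode-dependent fields (``asymmetry``, ``trunk_coupling``,
    ``between_subject_ap_var_inflation``) default to the healthy values
    (0, 0, 1) in healthy mode and to (0.25, 0.3, 2) in parkinsonian mode
    when left unset.
    """

    n_subjects: int = 23
    mode: str = "healthy"
    cycle_duration: float = 1.1  # seconds per gait cycle
    n_cycles: int = 2  # trials span ~2.2 s, one full cycle per side
    sampling_rate: float = 120.0
    n_harmonics: int = 3
    signature_scale: float = 0.15  # subject phase/mixing perturbation scale
    trial_noise_scale: float = 0.05  # within-subject trial variation scale
    asymmetry: float | None = None
    trunk_coupling: float | None = None
    coupling_sd: float = 0.18  # between-subject SD of the coupling
    coupling_marker_sd: float = 0.12  # independent per-limb-marker spread
    dysregulation: float | None = None  # within-trial variability factor
    between_subject_ap_var_inflation: float | None = None
    latent_share: float = 0.8
    score_intercept: float = 5.0
    score_slope: float = 60.0
    score_noise: float = 3.0
    seed: int = 0
    marker_set: MarkerSet = field(default_factory=default_marker_set)

    def __post_init__(self) -> None:
        if self.mode not in ("healthy", "parkinsonian"):
            raise ValueError("mode must be 'healthy' or 'parkinsonian'")
        pd_mode = self.mode == "parkinsonian"
        if self.asymmetry is None:
            self.asymmetry = 0.25 if pd_mode else 0.0
        if self.trunk_coupling is None:
            self.trunk_coupling = 0.3 if pd_mode else 0.0
        if self.between_subject_ap_var_inflation is None:
            self.between_subject_ap_var_inflation = 2.0 if pd_mode else 1.0
        if self.dysregulation is None:
            self.dysregulation = 1.5 if pd_mode else 1.0
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        for name in ("signature_scale", "trial_noise_scale", "asymmetry",
                     "trunk_coupling", "coupling_sd", "score_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.latent_share < 1:
            raise ValueError("latent_share must lie in (0, 1)")
        if self.sampling_rate * self.cycle_duration < 60:
            raise ValueError("need at least 60 frames per gait cycle")

    @property
    def n_frames(self) -> int:
        return int(round(
            self.sampling_rate * self.cycle_duration * self.n_cycles
        ))

    @property
    def group_label(self) -> str:
        return "PD" if self.mode == "parkinsonian" else "HC"


def _profiles(spec: CohortSpec, axis: str) -> tuple[np.ndarray, np.ndarray]:
    """(weights, phases) arrays of shape (modules, n_harmonics)."""
    w = _TEMPLATE_PROFILES[axis]["weights"]
    p = _TEMPLATE_PROFILES[axis]["phases"]
    h = spec.n_harmonics
    if h <= 3:
        return w[:, :h], p[:, :h]
    extra = h - 3
    w_ext = np.column_stack(
        [w] + [w[:, -1:] * (0.5 ** (i + 1)) for i in range(extra)]
    )
    p_ext = np.column_stack([p] + [p[:, -1:]] * extra)
    return w_ext, p_ext


def _community_labels(spec: CohortSpec) -> dict[str, np.ndarray]:
    n = len(spec.marker_set)
    out = {}
    for axis in AXES:
        labels = np.zeros(n, dtype=int)
        for cid, members in enumerate(_TEMPLATE_COMMUNITIES[axis]):
            labels[list(members)] = cid
        out[axis] = labels
    return out


def _template_amplitudes(spec: CohortSpec) -> np.ndarray:
    """(markers, 3 axes) base amplitudes; bilaterally symmetric."""
    ms = spec.marker_set
    return np.array(
        [_GROUP_AMPLITUDES[ms.anatomical_group[lab]] for lab in ms.labels]
    )


def _subject_params(spec: CohortSpec) -> dict:
    """All subject-level (trial-stable) draws, deterministic in spec.seed."""
    ss = np.random.SeedSequence(spec.seed)
    sub_ss, _trial_ss, demo_ss = ss.spawn(3)
    rng = np.random.default_rng(sub_ss)
    n, h = spec.n_subjects, spec.n_harmonics
    n_mark = len(spec.marker_set)
    # phase dispersion mapping: a relative scale s corresponds to s*pi/2
    # radians of subject-level phase SD (trial jitter uses the same mapping,
    # so test-retest contrast depends only on the scale ratio)
    phase_sd = spec.signature_scale * np.pi / 4
    # per-axis inflation of between-subject variability (disease: AP)
    infl = np.array([
        1.0,
        np.sqrt(spec.between_subject_ap_var_inflation),
        1.0,
    ])  # order (ML, AP, V)

    params = {
        # module-level phase offsets: (subjects, axes, modules, harmonics)
        "module_phase": rng.normal(0, phase_sd, (n, 3, 3, h)) * infl[None, :, None, None],
        # marker private phase offsets: (subjects, markers, axes, harmonics)
        "private_phase": rng.normal(0, phase_sd, (n, n_mark, 3, h)) * infl[None, None, :, None],
        # marker timing lag on the shared latent (rad at the fundamental)
        "latent_lag": rng.normal(0, phase_sd / 2, (n, n_mark, 3)) * infl[None, None, :],
        # multiplicative perturbation of the latent (coordination) weight
        "mix_jitter": rng.normal(0, spec.signature_scale / 2, (n, n_mark, 3)) * infl[None, None, :],
        # overall amplitude factor (no effect on correlations; realism)
        "amp_factor": np.exp(rng.normal(0, spec.signature_scale, (n, n_mark, 3))),
        # subject-level phase offsets of the axial rigidity drive
        "rigidity_phase": rng.normal(0, phase_sd, (n, 3, h)),
    }
    couplings = np.zeros(n)
    if spec.trunk_coupling > 0:
        couplings = np.clip(
            rng.normal(spec.trunk_coupling, spec.coupling_sd, n), 0, None
        )
    params["couplings"] = couplings
    # hierarchical per-marker couplings: the subject level drives the degree
    # and the motor score, the independent marker level decorrelates
    # limb-limb edges so trunk-limb edges carry the first-order reliability
    per_marker = couplings[:, None] + rng.normal(
        0, spec.coupling_marker_sd, (n, n_mark)
    )
    if spec.trunk_coupling == 0:
        per_marker = np.zeros((n, n_mark))
    params["coupling_per_marker"] = np.clip(per_marker, 0, None)
    demo = np.random.default_rng(demo_ss)
    params["age"] = demo.integers(45, 81, n)
    params["sex"] = np.where(demo.random(n) < 0.55, "M", "F")
    params["education"] = demo.integers(5, 21, n)
    params["score_noise"] = demo.normal(0, spec.score_noise, n)
    return params


def planted_truth(spec: CohortSpec) -> dict:
    """Ground-truth record of a cohort, for recovery tests.

    Contains the per-subject trunk-coupling realizations, the template
    community labels per axis, the (bilaterally symmetric in healthy mode)
    template amplitudes, and the subject signature draws.
    """
    params = _subject_params(spec)
    return {
        "couplings": params["couplings"],
        "communities": _community_labels(spec),
        "template_amplitudes": _template_amplitudes(spec),
        "module_phase": params["module_phase"],
        "private_phase": params["private_phase"],
        "motor_scores": _motor_scores(spec, params),
    }


def _motor_scores(spec: CohortSpec, params: dict) -> np.ndarray:
    raw = (spec.score_intercept
           + spec.score_slope * params["couplings"]
           + params["score_noise"])
    return np.clip(raw, 0.0, None)


def _trial_positions(
    spec: CohortSpec,
    params: dict,
    subject: int,
    trial_rng: np.random.Generator,
) -> np.ndarray:
    """Positions (frames, markers, 3) for one trial of one subject."""
    ms = spec.marker_set
    n_mark = len(ms)
    h = spec.n_harmonics
    harmonics = np.arange(1, h + 1)
    freq = 1.0 / spec.cycle_duration
    t = np.arange(spec.n_frames) / spec.sampling_rate
    omega_t = 2 * np.pi * freq * t[:, None] * harmonics[None, :]  # (F, H)

    comm = _community_labels(spec)
    amps = _template_amplitudes(spec)
    jitter_sd = spec.trial_noise_scale * spec.dysregulation * np.pi / 4
    theta = trial_rng.uniform(0, 2 * np.pi)  # gait-phase of trial onset
    left = np.array([ms.side[lab] == "left" for lab in ms.labels])
    distal = np.array(
        [ms.anatomical_group[lab] in _COUPLING_GROUPS for lab in ms.labels]
    )
    t10 = ms.index(ms.trunk_anchor)

    w_lat_base = np.sqrt(spec.latent_share)
    w_priv = np.sqrt(1 - spec.latent_share)

    positions = np.empty((spec.n_frames, n_mark, 3))
    for ax_i, axis in enumerate(AXES):
        weights, base_phase = _profiles(spec, axis)  # (modules, H)
        labels = comm[axis]
        norm = np.sqrt((weights**2).sum(axis=1) / 2.0)  # unit-RMS latents

        mod_w = weights[labels] / norm[labels, None]  # (markers, H)
        mod_p = (base_phase[labels]
                 + params["module_phase"][subject, ax_i, labels, :])

        lag = params["latent_lag"][subject, :, ax_i]
        jit_lat = trial_rng.normal(0, jitter_sd, (n_mark, h))
        lat_phase = (mod_p
                     + harmonics[None, :] * (lag[:, None] + theta)
                     + jit_lat)
        latent = np.sin(omega_t[:, None, :] + lat_phase[None, :, :])
        latent = (latent * mod_w[None, :, :]).sum(axis=2)  # (F, markers)

        priv_p = (params["private_phase"][subject, :, ax_i, :]
                  + harmonics[None, :] * theta
                  + trial_rng.normal(0, jitter_sd, (n_mark, h)))
        # private template phases: fixed anatomy, independent of cohort seed
        anat = np.random.default_rng(12345 + ax_i)
        priv_p = priv_p + anat.uniform(0, 2 * np.pi, (n_mark, h))
        private = np.sin(omega_t[:, None, :] + priv_p[None, :, :])
        private = (private * mod_w[None, :, :]).sum(axis=2)

        w_lat = w_lat_base * np.exp(params["mix_jitter"][subject, :, ax_i])
        w_lat = np.where(
            (labels == labels[t10]) & (np.arange(n_mark) == t10),
            np.sqrt(0.95), w_lat,
        )  # the trunk anchor hews closest to its module latent
        if spec.asymmetry > 0:
            w_lat = np.where(left, w_lat * (1 - spec.asymmetry), w_lat)

        # gait mixture, normalized to unit RMS per marker so that coupling
        # shares are comparable across modules and body sides
        mixture = w_lat[None, :] * latent + w_priv * private
        mixture = mixture / np.sqrt(w_lat**2 + w_priv**2)[None, :]

        # axial rigidity drive: always present in the trunk anchor's motion
        # (a subject-specific trait), coupled into the distal channels only
        # in disease mode
        rw = _RIGIDITY_WEIGHTS[:h] / np.sqrt(
            (_RIGIDITY_WEIGHTS[:h] ** 2).sum() / 2.0
        )
        rp = (_RIGIDITY_PHASES[axis][:h]
              + params["rigidity_phase"][subject, ax_i, :h]
              + harmonics * theta)
        rigidity = (np.sin(omega_t + rp[None, :]) * rw[None, :]).sum(axis=1)
        target = np.zeros(n_mark)  # rigidity share of the acceleration
        target[t10] = _RIGIDITY_T10_SHARE
        if spec.trunk_coupling > 0 and axis in ("ML", "AP"):
            target = target + params["coupling_per_marker"][subject] * distal
        target = np.clip(target, 0.0, 0.9)
        # convert acceleration-share targets to position-scale shares
        h2 = harmonics.astype(float) ** 2
        rv_acc = ((rw * h2) ** 2).sum() / 2.0
        mv_acc = ((mod_w * h2[None, :]) ** 2).sum(axis=1) / 2.0
        share = target * np.sqrt(mv_acc) / np.sqrt(
            rv_acc * (1 - target**2) + target**2 * mv_acc
        )
        signal = (np.sqrt(1 - share**2)[None, :] * mixture
                  + share[None, :] * rigidity[:, None])

        amp = amps[:, ax_i] * params["amp_factor"][subject, :, ax_i]
        if spec.asymmetry > 0:
            amp = np.where(left, amp * (1 - spec.asymmetry / 2), amp)

        # additive trial noise, band-limited to the gait harmonics
        noise_p = trial_rng.uniform(0, 2 * np.pi, (n_mark, h))
        noise = np.sin(omega_t[:, None, :] + noise_p[None, :, :])
        noise = (noise * mod_w[None, :, :]).sum(axis=2)
        signal = signal + spec.trial_noise_scale * spec.dysregulation * noise

        positions[:, :, ax_i] = amp[None, :] * signal

    # static posture offsets and forward progression
    for i, lab in enumerate(ms.labels):
        side = ms.side[lab]
        positions[:, i, 0] += {"left": -0.1, "right": 0.1, "midline": 0.0}[side]
        positions[:, i, 1] += _WALK_SPEED * t
        positions[:, i, 2] += _GROUP_HEIGHTS[ms.anatomical_group[lab]]
    return positions


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[MarkerTrial], pd.DataFrame]:
    """Generate two trials per subject plus the subject metadata table."""
    params = _subject_params(spec)
    ss = np.random.SeedSequence(spec.seed)
    _sub_ss, trial_ss, _demo_ss = ss.spawn(3)
    trial_seeds = trial_ss.spawn(spec.n_subjects)
    scores = _motor_scores(spec, params)

    trials: list[MarkerTrial] = []
    rows = []
    for s in range(spec.n_subjects):
        sid = f"{spec.group_label}{s + 1:02d}"
        srng = np.random.default_rng(trial_seeds[s])
        for session in ("test", "retest"):
            positions = _trial_positions(spec, params, s, srng)
            trials.append(
                MarkerTrial(
                    subject_id=sid,
                    session=session,
                    positions=positions,
                    sampling_rate=spec.sampling_rate,
                    marker_set=spec.marker_set,
                )
            )
        rows.append(
            {
                "subject_id": sid,
                "group": spec.group_label,
                "age": int(params["age"][s]),
                "sex": str(params["sex"][s]),
                "education": int(params["education"][s]),
                "motor_score": float(scores[s]),
            }
        )
    return trials, pd.DataFrame(rows)


def planted_edge_cohort(
    n_subjects: int = 23,
    n_signature: int = 20,
    signature_sd: float = 2.0,
    trial_sd: float = 0.1,
    seed: int = 0,
    marker_set: MarkerSet | None = None,
) -> tuple[list[EdgeVector], list[EdgeVector], np.ndarray]:
    """Edge vectors with a planted subject signature on a few edges.

    ``n_signature`` edges carry stable subject-specific offsets (high
    test-retest ICC); the rest are session-independent noise (ICC ~ 0).
    Returns (test, retest, signature_edge_indices) for edge-selection
    recovery tests.
    """
    ms = marker_set or default_marker_set()
    pairs = edge_index_pairs(ms.labels)
    n_edges = len(pairs)
    rng = np.random.default_rng(seed)
    signature_idx = np.sort(
        rng.choice(n_edges, size=n_signature, replace=False)
    )
    offsets = rng.normal(0, signature_sd, (n_subjects, n_signature))

    def session_vectors(session: str) -> list[EdgeVector]:
        values = rng.normal(0, 1.0, (n_subjects, n_edges))
        values[:, signature_idx] = offsets + rng.normal(
            0, trial_sd, (n_subjects, n_signature)
        )
        return [
            EdgeVector(
                values=values[i],
                edge_index=pairs,
                subject_id=f"S{i + 1:02d}",
                session=session,
            )
            for i in range(n_subjects)
        ]

    return session_vectors("test"), session_vectors("retest"), signature_idx
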