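"""Synthetic motion-contaminated multi-ROI BOLD-like cohorts.

The generator emulates the statistical structure of a developmental
resting-state functional connectivity study of children (ages 7-14) with
ADHD subtypes:

* a 160-ROI geometry in a brain-like bounding box with six partially
  spatially coherent network labels (default, fronto-parietal,
  cingulo-opercular, sensorimotor, occipital, cerebellum);
* clean signal drawn from a multivariate normal whose covariance is built
  in Fisher-z space from network blocks, a distance-decaying proximity
  term, planted linear age trends (+beta on designated long-range
  within-network edges, -beta on designated short-range between-network
  edges), and subtype-specific offsets (default-network edges for ADHD-C,
  fronto-parietal/cerebellar edges for ADHD-I, sensorimotor edges for
  both), mapped back to correlation space and projected to the nearest
  positive-definite correlation matrix;
* a per-subject motion spike process: Bernoulli spike frames add
  displacement pulses to the six realignment parameters and a shared
  artifact component with spatially smooth ROI loadings, so proximal ROI
  pairs share more artifact (the premise of distance-dependent motion
  confounds); per-subject spike propensity correlates negatively with age;
* each ROI expanded to several noisy channel replicates on a mode-1000
  intensity scale so DVARS is computable, plus nuisance channels
  (global / white-matter / ventricle analogs).

Every subject carries a ground-truth record (clean target z-matrix, spike
frames, true mean FD, planted per-edge effects) for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from . import motion as _motion
from .io import DIAGNOSES, RealignmentSeries, RoiSet
from .connectivity import edge_index

__all__ = [
    "SyntheticConfig",
    "GroundTruthRecord",
    "SubjectData",
    "Cohort",
    "generate_roi_geometry",
    "generate_subject",
    "generate_cohort",
]

_SAVE_LOAD = ["save_cohort", "load_cohort"]
__all__ += _SAVE_LOAD

NETWORK_NAMES = (
    "cerebellum",
    "occipital",
    "sensorimotor",
    "default",
    "cingulo-opercular",
    "fronto-parietal",
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Units: distances in mm, ages in years, edge effects in Fisher-z units,
    spike magnitudes in mm of framewise displacement, channel intensities
    on a mode-1000-like scale.
    """

    n_per_group: int = 40
    groups: tuple[str, ...] = DIAGNOSES
    age_range: tuple[float, float] = (7.0, 14.0)
    n_rois: int = 160
    n_networks: int = 6
    n_frames: int = 200
    tr_seconds: float = 2.5
    # baseline covariance (Fisher-z space)
    rho_within: float = 0.35
    rho_between: float = 0.05
    proximity_weight: float = 0.25
    proximity_decay_mm: float = 30.0
    ar_phi: float = 0.15
    pd_floor: float = 1e-4
    # planted age trends
    age_slope: float = 0.025
    n_age_edges: int = 150
    long_range_min_mm: float = 60.0
    short_range_min_mm: float = 15.0
    short_range_max_mm: float = 45.0
    # planted subtype offsets
    delta_combined: float = -0.10
    delta_inattentive: float = -0.10
    delta_sensorimotor: float = -0.06
    # motion spike process
    spike_rate_mean: float = 0.10
    propensity_sigma: float = 0.9
    rho_age_motion: float = -0.45
    spike_log_mm: float = -1.1
    spike_log_sigma: float = 0.5
    drift_sigma_mm: float = 0.005
    # artifact model (correlated component entering the ROI signal)
    artifact_gain: float = 4.0
    artifact_decay_mm: float = 60.0
    # channel expansion (DVARS); the disruption term is the echo-planar
    # signal-loss analog: it drives DVARS but not the ROI signal
    channels_per_roi: int = 3
    signal_amplitude: float = 1.5
    channel_noise: float = 1.0
    dvars_disruption_gain: float = 15.0
    baseline_intensity: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho_within", "rho_between"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must be in (-1, 1), got {v}")
        if not -1.0 < self.rho_age_motion < 1.0:
            raise ValueError("rho_age_motion must be in (-1, 1)")
        if self.n_frames < 40:
            raise ValueError("n_frames must be >= 40")
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if self.n_networks > self.n_rois:
            raise ValueError("n_networks cannot exceed n_rois")
        if not 0 <= self.spike_rate_mean < 1:
            raise ValueError("spike_rate_mean must be in [0, 1)")


@dataclass
class GroundTruthRecord:
    """Planted structure for one synthetic subject."""

    clean_z: np.ndarray          # post-projection target z matrix (R x R)
    spike_frames: np.ndarray     # frame indices with motion spikes
    true_mean_fd: float
    age_effect: np.ndarray       # per-edge planted age slope (z/yr), condensed
    group_offset: np.ndarray     # per-edge planted diagnosis offset (z), condensed


@dataclass
class SubjectData:
    """Everything one synthetic subject contributes to the pipeline."""

    subject_id: str
    age: float
    diagnosis: str
    site: str
    sex: str
    iq: float
    realignment: RealignmentSeries
    roi_ts: np.ndarray           # R x T cleaned-scale ROI signal (+ artifact)
    channels: np.ndarray         # (R * channels_per_roi) x T intensity channels
    nuisance: np.ndarray         # 3 x T (global / wm / ventricle analogs)
    tr_seconds: float


@dataclass
class Cohort:
    """A generated cohort: ROI geometry, phenotype table, subject bundles,
    and ground-truth records (in table order)."""

    rois: RoiSet
    table: pd.DataFrame
    subjects: list[SubjectData]
    ground_truth: list[GroundTruthRecord]
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def generate_roi_geometry(n_rois: int, n_networks: int, seed: int) -> RoiSet:
    """ROI centers in a +-70 x +-100 x +-70 mm box with spatially coherent
    network labels from k-means clustering of the coordinates.

    Clusters are named in order of ascending centroid z (inferior first),
    so the lowest cluster plays the cerebellum when six networks are used.
    """
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    if n_networks > n_rois:
        raise ValueError("more networks than ROIs")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(low=[-70, -100, -70], high=[70, 100, 70], size=(n_rois, 3))
    if n_networks == 1:
        labels = np.zeros(n_rois, dtype=int)
        order = np.array([0])
    else:
        km = KMeans(n_clusters=n_networks, n_init=4,
                    random_state=int(rng.integers(2 ** 31)))
        labels = km.fit_predict(coords)
        order = np.argsort(km.cluster_centers_[:, 2], kind="stable")
    if n_networks == len(NETWORK_NAMES):
        names = NETWORK_NAMES
    else:
        names = tuple(f"net{i + 1:02d}" for i in range(n_networks))
    rank = np.empty(n_networks, dtype=int)
    rank[order] = np.arange(n_networks)
    table = pd.DataFrame(
        {
            "id": [f"roi{i + 1:03d}" for i in range(n_rois)],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "network": [names[rank[l]] for l in labels],
        }
    )
    return RoiSet(table=table)


# ---------------------------------------------------------------------------
# planted-effect plan (cohort level)
# ---------------------------------------------------------------------------

@dataclass
class EffectPlan:
    """Cohort-level planted edge effects in condensed edge space."""

    age_effect: np.ndarray       # z per year, signed, condensed
    combined_offset: np.ndarray  # z offsets applied to ADHD-C subjects
    inattentive_offset: np.ndarray
    age_pos_edges: np.ndarray    # indices: long-range within-network, +beta
    age_neg_edges: np.ndarray    # indices: short-range between-network, -beta
    default_nodes: np.ndarray    # ROI indices of the default network


def _plan_effects(rois: RoiSet, config: SyntheticConfig, rng: np.random.Generator) -> EffectPlan:
    nets = rois.networks
    dist = pdist(rois.coords)
    iu, ju = edge_index(rois.n_rois)
    within = nets[iu] == nets[ju]
    n_edges = dist.size

    def pick(candidates: np.ndarray, k: int) -> np.ndarray:
        idx = np.flatnonzero(candidates)
        if idx.size == 0:
            return idx
        return np.sort(rng.choice(idx, size=min(k, idx.size), replace=False))

    pos = pick(within & (dist >= config.long_range_min_mm), config.n_age_edges)
    neg = pick(
        (~within)
        & (dist >= config.short_range_min_mm)
        & (dist <= config.short_range_max_mm),
        config.n_age_edges,
    )
    age_effect = np.zeros(n_edges)
    age_effect[pos] = config.age_slope
    age_effect[neg] = -config.age_slope

    def both_in(names: set[str]) -> np.ndarray:
        member = np.isin(nets, list(names))
        return member[iu] & member[ju]

    combined = np.zeros(n_edges)
    inattentive = np.zeros(n_edges)
    combined[both_in({"default"})] = config.delta_combined
    inattentive[both_in({"fronto-parietal", "cerebellum"})] = config.delta_inattentive
    sm = both_in({"sensorimotor"})
    combined[sm] = config.delta_sensorimotor
    inattentive[sm] = config.delta_sensorimotor
    return EffectPlan(
        age_effect=age_effect,
        combined_offset=combined,
        inattentive_offset=inattentive,
        age_pos_edges=pos,
        age_neg_edges=neg,
        default_nodes=np.flatnonzero(nets == "default"),
    )


def _base_z(rois: RoiSet, config: SyntheticConfig) -> np.ndarray:
    """Baseline Fisher-z matrix: network blocks plus proximity term."""
    nets = rois.networks
    dmat = squareform(pdist(rois.coords))
    within = nets[:, None] == nets[None, :]
    z = np.where(within, np.arctanh(config.rho_within), np.arctanh(config.rho_between))
    z = z + config.proximity_weight * np.exp(-dmat / config.proximity_decay_mm)
    np.fill_diagonal(z, 0.0)
    return z


def _nearest_pd_correlation(r: np.ndarray, floor: float) -> np.ndarray:
    """Eigenvalue clipping at a small floor, then renormalization to a
    correlation matrix."""
    sym = (r + r.T) / 2.0
    np.fill_diagonal(sym, 1.0)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= floor:
        return sym
    vals = np.clip(vals, floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    if np.linalg.eigvalsh(fixed).min() < floor / 10:
        raise RuntimeError(
            "nearest-PD projection failed tolerance; "
            f"min eigenvalue {np.linalg.eigvalsh(fixed).min():.3g}"
        )
    return fixed


# ---------------------------------------------------------------------------
# subject generation
# ---------------------------------------------------------------------------

def _ar1_sample(chol: np.ndarray, phi: float, n_frames: int,
                rng: np.random.Generator) -> np.ndarray:
    """Sample an AR(1)-in-time multivariate normal with stationary
    covariance ``chol @ chol.T``."""
    n = chol.shape[0]
    innov = chol @ rng.standard_normal((n, n_frames))
    if phi == 0:
        return innov
    x = np.empty_like(innov)
    x[:, 0] = innov[:, 0]
    scale = np.sqrt(1.0 - phi ** 2)
    for t in range(1, n_frames):
        x[:, t] = phi * x[:, t - 1] + scale * innov[:, t]
    return x


def _spike_realignment(n_frames: int, spike_frames: np.ndarray,
                       magnitudes: np.ndarray, config: SyntheticConfig,
                       rng: np.random.Generator) -> RealignmentSeries:
    """Realignment parameters: slow random-walk drift plus one-frame
    displacement pulses whose FD contribution equals the spike magnitude."""
    drift = np.cumsum(rng.normal(0.0, config.drift_sigma_mm, (n_frames, 6)), axis=0)
    drift[:, 3:] /= _motion.DEFAULT_RADIUS_MM  # comparable arc-length scale
    params = drift
    for t, m in zip(spike_frames, magnitudes):
        w = np.abs(rng.standard_normal(6))
        w /= w.sum()
        pulse = m * w
        pulse[3:] /= _motion.DEFAULT_RADIUS_MM  # rotations in radians
        params[t] += pulse
    return RealignmentSeries(params=params, tr_seconds=config.tr_seconds,
                             dialect="generic", run_id="synthetic")


def generate_subject(age: float, diagnosis: str, rois: RoiSet, plan: EffectPlan,
                     config: SyntheticConfig, seed: int | np.random.SeedSequence,
                     spike_prob: float | None = None,
                     subject_id: str = "sub") -> tuple[SubjectData, GroundTruthRecord]:
    """Generate one subject's realignment series, ROI/channel time series,
    nuisance channels, and ground truth.

    ``spike_prob`` overrides the per-frame spike probability; the cohort
    generator uses it to impose the age-motion confound at group level.
    """
    lo, hi = config.age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside configured range {config.age_range}")
    if diagnosis not in config.groups:
        raise ValueError(f"unknown diagnosis {diagnosis!r}")
    rng = np.random.default_rng(seed)
    n, T = rois.n_rois, config.n_frames
    iu, ju = edge_index(n)

    # --- target covariance in z space -------------------------------------
    z = _base_z(rois, config)
    age_mid = 0.5 * (lo + hi)
    edge_offsets = plan.age_effect * (age - age_mid)
    group = np.zeros_like(plan.age_effect)
    if diagnosis == "ADHD-C":
        group = plan.combined_offset
    elif diagnosis == "ADHD-I":
        group = plan.inattentive_offset
    z[iu, ju] += edge_offsets + group
    z[ju, iu] = z[iu, ju]
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    r = _nearest_pd_correlation(r, config.pd_floor)
    clean_z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(clean_z, 0.0)

    # --- clean signal ------------------------------------------------------
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(n))
    x = _ar1_sample(chol, config.ar_phi, T, rng)

    # --- motion spikes & artifact -----------------------------------------
    p = config.spike_rate_mean if spike_prob is None else spike_prob
    spikes = np.flatnonzero(rng.random(T) < p)
    magnitudes = rng.lognormal(config.spike_log_mm, config.spike_log_sigma,
                               size=spikes.size)
    realign = _spike_realignment(T, spikes, magnitudes, config, rng)

    # correlated artifact: a fresh spatially smooth field per spike frame,
    # so the artifact adds covariance proportional to exp(-d / decay) --
    # proximal ROI pairs share systematically more artifact
    roi_ts = x.copy()
    s = np.zeros(T)
    if spikes.size:
        dmat = squareform(pdist(rois.coords))
        k_art = np.exp(-dmat / config.artifact_decay_mm) + 1e-6 * np.eye(n)
        chol_art = np.linalg.cholesky(k_art)
        fields = chol_art @ rng.standard_normal((n, spikes.size))
        # remove each field's spatial mean: proximal pairs keep shared
        # artifact while distant pairs acquire a slight deflation, the
        # short-inflated / long-deflated profile of motion artifact
        fields -= fields.mean(axis=0, keepdims=True)
        amp = config.artifact_gain * magnitudes
        roi_ts[:, spikes] += fields * amp[None, :]
        s[spikes] = amp

    # --- channels & nuisance ----------------------------------------------
    reps = np.repeat(roi_ts, config.channels_per_roi, axis=0)
    channels = (
        config.baseline_intensity
        + config.signal_amplitude * reps
        + config.channel_noise * rng.standard_normal(reps.shape)
    )
    if spikes.size:
        # per-channel intensity disruption at spike frames (signal-loss
        # analog); visible to DVARS only, never to the ROI series
        burst = rng.standard_normal((reps.shape[0], spikes.size))
        channels[:, spikes] += config.dvars_disruption_gain * magnitudes[None, :] * burst
    global_sig = roi_ts.mean(axis=0) + 0.1 * rng.standard_normal(T)
    wm = _ar1_sample(np.eye(1), config.ar_phi, T, rng)[0] + 0.2 * s
    vent = _ar1_sample(np.eye(1), config.ar_phi, T, rng)[0] + 0.2 * s
    nuisance = np.vstack([global_sig, wm, vent])

    fd = _motion.compute_fd(realign)
    subject = SubjectData(
        subject_id=subject_id,
        age=float(age),
        diagnosis=diagnosis,
        site="site1",
        sex="F",
        iq=float("nan"),
        realignment=realign,
        roi_ts=roi_ts,
        channels=channels,
        nuisance=nuisance,
        tr_seconds=config.tr_seconds,
    )
    truth = GroundTruthRecord(
        clean_z=clean_z,
        spike_frames=spikes,
        true_mean_fd=float(fd.mean()),
        age_effect=plan.age_effect.copy(),
        group_offset=group.copy(),
    )
    return subject, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full cohort with the configured group sizes.

    Ages are uniform on the configured range; per-subject spike propensity
    is lognormal around the mean spike rate with a latent Gaussian that
    correlates negatively with age (strength ``rho_age_motion``), which is
    what couples motion artifact to age at the group level.
    """
    master = np.random.SeedSequence(config.seed)
    geom_seed, plan_seed, subj_seed, pheno_seed = master.spawn(4)
    rois = generate_roi_geometry(config.n_rois, config.n_networks,
                                 seed=int(geom_seed.generate_state(1)[0] % (2 ** 31)))
    plan_rng = np.random.default_rng(plan_seed)
    plan = _plan_effects(rois, config, plan_rng)

    n_total = config.n_per_group * len(config.groups)
    pheno_rng = np.random.default_rng(pheno_seed)
    lo, hi = config.age_range
    ages = pheno_rng.uniform(lo, hi, size=n_total)
    diagnoses = np.repeat(list(config.groups), config.n_per_group)
    sites = pheno_rng.choice(["siteA", "siteB"], size=n_total)
    sexes = pheno_rng.choice(["F", "M"], size=n_total)
    iqs = np.round(pheno_rng.normal(110.0, 12.0, size=n_total), 1)

    rho = abs(config.rho_age_motion)
    z_age = (ages - ages.mean()) / max(ages.std(), 1e-12)
    latent = (np.sign(config.rho_age_motion) * rho * z_age
              + np.sqrt(1 - rho ** 2) * pheno_rng.standard_normal(n_total))
    spike_probs = np.clip(
        config.spike_rate_mean
        * np.exp(config.propensity_sigma * latent - config.propensity_sigma ** 2 / 2),
        0.005,
        0.45,
    )
    if config.spike_rate_mean == 0:
        spike_probs = np.zeros(n_total)

    subjects: list[SubjectData] = []
    truths: list[GroundTruthRecord] = []
    child_seeds = subj_seed.spawn(n_total)
    for k in range(n_total):
        sid = f"sub{k + 1:04d}"
        subject, truth = generate_subject(
            ages[k], diagnoses[k], rois, plan, config, child_seeds[k],
            spike_prob=float(spike_probs[k]), subject_id=sid,
        )
        subject.site = str(sites[k])
        subject.sex = str(sexes[k])
        subject.iq = float(iqs[k])
        subjects.append(subject)
        truths.append(truth)

    table = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age": ages,
            "diagnosis": diagnoses,
            "site": sites,
            "sex": sexes,
            "iq": iqs,
            "spike_prob": spike_probs,
            "true_mean_fd": [t.true_mean_fd for t in truths],
        }
    )
    return Cohort(rois=rois, table=table, subjects=subjects,
                  ground_truth=truths, config=config)


# ---------------------------------------------------------------------------
# disk round trip (flat manifest layout)
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, outdir) -> None:
    """Write a cohort as flat text files with a manifest.

    Layout: ``rois.tsv``, ``phenotype.csv``, ``manifest.csv`` (subject ->
    file paths), per-subject realignment (generic dialect), ROI
    time-series, channel and nuisance matrices, and ``ground_truth.json``
    (spike frames, true mean FD, and the planted edge effects; the dense
    clean z-matrices stay in memory only).
    """
    import json
    from pathlib import Path

    from . import io as _io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_roi_table(out / "rois.tsv", cohort.rois)
    _io.write_phenotype(out / "phenotype.csv", cohort.table)
    rows = []
    for s in cohort.subjects:
        paths = {
            "realignment": f"{s.subject_id}_realign.txt",
            "timeseries": f"{s.subject_id}_ts.csv",
            "channels": f"{s.subject_id}_channels.csv",
            "nuisance": f"{s.subject_id}_nuisance.csv",
        }
        _io.write_realignment(out / paths["realignment"], s.realignment)
        _io.write_timeseries(out / paths["timeseries"], s.roi_ts)
        _io.write_timeseries(out / paths["channels"], s.channels)
        _io.write_timeseries(out / paths["nuisance"], s.nuisance)
        rows.append({"subject_id": s.subject_id, **paths})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    truth = {
        s.subject_id: {
            "spike_frames": t.spike_frames.tolist(),
            "true_mean_fd": t.true_mean_fd,
        }
        for s, t in zip(cohort.subjects, cohort.ground_truth)
    }
    truth["_planted_effects"] = {
        "age_effect_nonzero": np.flatnonzero(
            cohort.ground_truth[0].age_effect).tolist(),
        "age_effect_values": cohort.ground_truth[0].age_effect[
            np.flatnonzero(cohort.ground_truth[0].age_effect)].tolist(),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh)


def load_cohort(indir, config: SyntheticConfig | None = None) -> Cohort:
    """Load a cohort saved by :func:`save_cohort`.

    Ground-truth records carry the on-disk fields (spike frames, true
    mean FD); the dense clean z-matrices are not persisted and come back
    empty.
    """
    import json
    from pathlib import Path

    from . import io as _io

    src = Path(indir)
    rois = _io.read_roi_table(src / "rois.tsv")
    table = _io.read_phenotype(src / "phenotype.csv")
    manifest = pd.read_csv(src / "manifest.csv").set_index("subject_id")
    with open(src / "ground_truth.json") as fh:
        truth_data = json.load(fh)
    config = config or SyntheticConfig(n_rois=rois.n_rois)
    subjects, truths = [], []
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        files = manifest.loc[sid]
        realign = _io.read_realignment(src / files["realignment"],
                                       dialect="generic",
                                       tr_seconds=config.tr_seconds, run_id=sid)
        subjects.append(SubjectData(
            subject_id=sid,
            age=float(row["age"]),
            diagnosis=str(row["diagnosis"]),
            site=str(row["site"]),
            sex=str(row["sex"]),
            iq=float(row["iq"]) if not row.get("iq_missing", False) else float("nan"),
            realignment=realign,
            roi_ts=_io.read_timeseries(src / files["timeseries"], n_rois=rois.n_rois),
            channels=_io.read_timeseries(src / files["channels"]),
            nuisance=_io.read_timeseries(src / files["nuisance"]),
            tr_seconds=config.tr_seconds,
        ))
        t = truth_data[sid]
        truths.append(GroundTruthRecord(
            clean_z=np.zeros((0, 0)),
            spike_frames=np.asarray(t["spike_frames"], dtype=int),
            true_mean_fd=float(t["true_mean_fd"]),
            age_effect=np.zeros(0),
            group_offset=np.zeros(0),
        ))
    return Cohort(rois=rois, table=table, subjects=subjects,
                  ground_truth=truths, config=config)
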