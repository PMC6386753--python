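"""Synthetic resting-state cohorts with controllable planted effects.

The generator emulates the structure of a single-site case-control
resting-state fMRI study: two groups of subjects (by default 81
patients and 93 controls, the scale of the motivating cohort), each
subject a 4D BOLD-like volume built from ROI-level latent signals
broadcast to the member voxels of a ground-truth block parcellation,
plus i.i.d. voxel noise.

Per subject, each ROI's latent signal is the sum of

* a band-limited oscillation — a normalized sum of sinusoids at random
  frequencies inside 0.01-0.08 Hz with random phases, whose amplitude
  varies between subjects (this makes ALFF-type effects analytically
  controllable), and
* stationary AR(1) noise that is correlated *between* ROIs according to
  a compound-symmetry correlation matrix.

Group differences are planted two ways: an ``amplitude_shift`` (in
units of the between-subject amplitude SD) added to patients'
oscillation amplitude in a chosen fraction of ROIs, and a
``coupling_shift`` added to patients' inter-ROI noise correlation on a
chosen fraction of edges (positive-definiteness of the target matrix is
checked before any simulation). Confound variables (age, sex, TIV, mean
FD) can be correlated with group at a controllable strength.

Three synthetic atlases — the true block partition (labels dialect), a
smoothed network grouping of the blocks (maps dialect) and seed spheres
at the block centres (spheres dialect) — exercise all three atlas
dialects downstream. Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import Atlas, load_atlas
from .bold import BoldSeries, smooth_map_gaussian


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 81
    n_controls: int = 93
    shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 3.0
    t: int = 143
    tr_seconds: float = 2.0
    roi_grid: tuple[int, int, int] = (2, 2, 2)
    # noise model
    ar_coef: float = 0.3
    voxel_noise_sd: float = 1.0
    base_coupling: float = 0.2
    # band-limited oscillations
    osc_base_amplitude: float = 0.7
    osc_subject_sd: float = 0.2
    n_sinusoids: int = 3
    band: tuple[float, float] = (0.01, 0.08)
    # planted effects; with effect_mode="subtypes" each patient
    # expresses only one effect family (half amplitude, half coupling)
    # at full strength, emulating clinical heterogeneity — no single
    # feature family then separates every patient
    amplitude_shift: float = 0.0
    amplitude_roi_fraction: float = 0.1
    coupling_shift: float = 0.0
    coupling_edge_fraction: float = 0.1
    effect_mode: str = "uniform"
    # confounds
    confound_group_strength: float = 0.0
    severity_effect: float = 0.0
    sphere_radius_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t < 64:
            raise ValueError("t must be at least 64")
        if not np.isfinite(self.amplitude_shift):
            raise ValueError("amplitude_shift must be finite")

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    @property
    def n_rois(self) -> int:
        return int(np.prod(self.roi_grid))

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] *= self.voxel_size_mm
        return a


def ci_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Desk-scale preset: 80+80 subjects, 16^3 grid, 64 timepoints."""
    defaults = dict(n_patients=80, n_controls=80, t=64, seed=seed)
    defaults.update(overrides)
    return CohortSpec(**defaults)


def null_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Desk-scale cohort with no planted group difference."""
    return ci_cohort_spec(seed, amplitude_shift=0.0, coupling_shift=0.0,
                          **overrides)


def planted_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Desk-scale cohort with the standard planted effect: +1.5
    between-subject SD band amplitude in 10% of ROIs and +0.25 observed
    ROI correlation on 10% of ROI pairs — two statistically separate
    effect families, so full label recovery requires combining regional
    and connectivity sources."""
    defaults = dict(amplitude_shift=1.5, coupling_shift=0.25)
    defaults.update(overrides)
    return ci_cohort_spec(seed, **defaults)


def _roi_label_volume(spec: CohortSpec) -> np.ndarray:
    """Partition the grid into axis-aligned blocks, labels 1..n_rois."""
    shape = np.asarray(spec.shape)
    grid = np.asarray(spec.roi_grid)
    if np.any(shape % grid):
        raise ValueError("shape must be divisible by roi_grid")
    block = shape // grid
    labels = np.zeros(spec.shape, dtype=int)
    lab = 1
    for i in range(grid[0]):
        for j in range(grid[1]):
            for k in range(grid[2]):
                labels[
                    i * block[0]:(i + 1) * block[0],
                    j * block[1]:(j + 1) * block[1],
                    k * block[2]:(k + 1) * block[2],
                ] = lab
                lab += 1
    return labels


def _coupling_targets(spec: CohortSpec, rng) -> tuple[np.ndarray, list]:
    """Patient ROI-correlation matrix and the perturbed edge list.

    One correlation structure drives both the band-limited oscillations
    and the AR noise: resting-state functional connectivity is
    coherence of the low-frequency fluctuations themselves, so
    ``coupling_shift`` is a delta in observed ROI-correlation units."""
    n = spec.n_rois
    base = np.full((n, n), spec.base_coupling)
    np.fill_diagonal(base, 1.0)
    rows, cols = np.tril_indices(n, k=-1)
    n_edges = max(1, int(np.ceil(spec.coupling_edge_fraction * len(rows))))
    chosen = rng.choice(len(rows), size=n_edges, replace=False)
    patient = base.copy()
    edges = []
    for e in np.sort(chosen):
        i, j = int(rows[e]), int(cols[e])
        patient[i, j] += spec.coupling_shift
        patient[j, i] += spec.coupling_shift
        edges.append((i, j))
    for name, mat in (("control", base), ("patient", patient)):
        if np.linalg.eigvalsh(mat).min() <= 1e-8:
            raise ValueError(
                f"{name} target correlation matrix is not positive definite"
            )
    return patient, edges


def _affected_rois(spec: CohortSpec, rng) -> np.ndarray:
    n_aff = max(1, int(np.ceil(spec.amplitude_roi_fraction * spec.n_rois)))
    return np.sort(rng.choice(spec.n_rois, size=n_aff, replace=False))


def _in_band_amplitude(signal: np.ndarray, spec: CohortSpec) -> np.ndarray:
    """Single-sided in-band amplitude sum along the last axis (the same
    measure the ALFF stage applies to voxel series)."""
    t = signal.shape[-1]
    spectrum = np.abs(np.fft.rfft(signal, axis=-1)) / t
    spectrum[..., 1:] *= 2.0
    if t % 2 == 0:
        spectrum[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(t, d=spec.tr_seconds)
    keep = (freqs >= spec.band[0]) & (freqs <= spec.band[1])
    return spectrum[..., keep].sum(axis=-1)


def _smoothing_retention(spec: CohortSpec,
                         fwhm_mm: float = 4.0) -> tuple[float, float]:
    """How much of a ROI's own signal and of voxel white noise survives
    the pipeline's spatial smoothing on this geometry.

    Returns ``(lam, kappa)``: lam is the mean, over one block's voxels,
    of the smoothed own-block indicator (signal retention; the rest
    leaks in from neighbouring blocks), and kappa the standard-deviation
    ratio of smoothed vs raw white noise.
    """
    labels = _roi_label_volume(spec)
    own = labels == 1
    lam = float(
        smooth_map_gaussian(own.astype(float), spec.affine, fwhm_mm)[own]
        .mean()
    )
    rng = np.random.default_rng(0)
    white = rng.standard_normal(spec.shape)
    kappa = float(smooth_map_gaussian(white, spec.affine, fwhm_mm).std())
    return lam, kappa


def _calibrate_amplitude_delta(
    spec: CohortSpec, rng, n_sim: int = 384, n_vox: int = 24
) -> float:
    """Oscillation-amplitude increment realizing ``amplitude_shift``.

    The shift is specified in units of the between-subject standard
    deviation of the feature the pipeline actually measures: the
    ROI-averaged, within-subject z-scored voxel in-band amplitude under
    the null. A miniature simulation of that feature (``n_sim``
    subjects, all ROIs, ``n_vox`` voxels each, smoothing approximated
    by the geometry-derived signal/noise retention factors) estimates
    the null SD and the realized group shift, and the increment solving
    ``realized shift = amplitude_shift * null SD`` is found by secant
    iteration. Deterministic given the generator seed.
    """
    if spec.amplitude_shift == 0:
        return 0.0
    n, t, phi = spec.n_rois, spec.t, spec.ar_coef
    low, high = spec.band
    lam, kappa = _smoothing_retention(spec)
    times = np.arange(t) * spec.tr_seconds

    def latent(batch):
        amps = np.maximum(
            spec.osc_base_amplitude
            + rng.normal(0.0, spec.osc_subject_sd, size=(batch, n)),
            0.05,
        )
        freqs = rng.uniform(low * 1.1, high * 0.95,
                            size=(batch, n, spec.n_sinusoids))
        phases = rng.uniform(0, 2 * np.pi, size=(batch, n, spec.n_sinusoids))
        osc = np.sin(
            2 * np.pi * freqs[..., None] * times + phases[..., None]
        ).sum(axis=2) / np.sqrt(spec.n_sinusoids / 2.0)
        innov = rng.standard_normal((batch, n, t))
        noise = np.empty((batch, n, t))
        noise[..., 0] = innov[..., 0]
        scale = np.sqrt(1.0 - phi**2)
        for i in range(1, t):
            noise[..., i] = phi * noise[..., i - 1] + scale * innov[..., i]
        return amps, osc, noise

    amps, osc, noise = latent(n_sim)
    white = rng.normal(0.0, spec.voxel_noise_sd, size=(n_sim, n, n_vox, t))
    # leakage from a neighbouring block: use the next ROI's latent signal
    neigh = np.roll(np.arange(n), 1)

    def roi_features(a):
        z = a[..., None] * osc + noise                      # (sim, n, t)
        mixed = lam * z + (1.0 - lam) * z[:, neigh, :]
        vox = mixed[:, :, None, :] + kappa * white
        amp = _in_band_amplitude(vox, spec)                  # (sim, n, vox)
        flat = amp.reshape(amp.shape[0], -1)
        mu = flat.mean(axis=1)[:, None, None]
        sd = flat.std(axis=1)[:, None, None]
        return ((amp - mu) / sd).mean(axis=2)                # (sim, n)

    base = roi_features(amps)[:, 0]
    sd_null = float(base.std(ddof=1))
    target = spec.amplitude_shift * sd_null

    def realized(delta):
        bumped = amps.copy()
        bumped[:, 0] += delta
        return float(roi_features(bumped)[:, 0].mean() - base.mean())

    # secant iteration on the monotone realized-shift curve
    d0 = spec.amplitude_shift * spec.osc_subject_sd
    r0 = realized(d0)
    d1 = d0 * target / max(r0, 1e-9)
    for _ in range(3):
        r1 = realized(d1)
        if abs(r1 - target) < 0.02 * target or r1 == r0:
            break
        d0, r0, d1 = d1, r1, d1 + (target - r1) * (d1 - d0) / (r1 - r0)
    return float(d1)


def _draw_frequencies(
    spec: CohortSpec, rng: np.random.Generator, n_series: int
) -> np.ndarray:
    """Stratified oscillation frequencies inside the band.

    One frequency is drawn per equal-width slot of the band and the
    slots are shuffled across series, guaranteeing a minimum spectral
    separation so that cross terms between different lines average out
    of long-run empirical correlations (iid draws can place two lines
    closer than 1/t apart, leaving persistent beat terms)."""
    total = n_series * spec.n_sinusoids
    lo, hi = spec.band[0] * 1.1, spec.band[1] * 0.95
    width = (hi - lo) / total
    freqs = lo + width * (np.arange(total) + 0.1 + 0.8 * rng.random(total))
    rng.shuffle(freqs)
    return freqs.reshape(n_series, spec.n_sinusoids)


def simulate_roi_signals(
    spec: CohortSpec,
    rng: np.random.Generator,
    express_amplitude: bool,
    express_coupling: bool,
    affected_rois: np.ndarray,
    chol_control: np.ndarray,
    chol_patient: np.ndarray,
    amplitude_delta: float = 0.0,
    t: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One subject's ROI latent signals.

    Returns ``(signals (n_rois, t), amplitudes (n_rois,), implied_cov)``.
    Both the oscillations and the AR noise carry the group's ROI
    correlation matrix C = chol @ chol.T, so the model-implied ROI
    covariance (which the empirical covariance approaches as t grows)
    is ``diag(a) C diag(a) + C`` with a the oscillation amplitudes.
    """
    n = spec.n_rois
    t = t or spec.t
    low, high = spec.band
    chol = chol_patient if express_coupling else chol_control

    amplitudes = spec.osc_base_amplitude + rng.normal(
        0.0, spec.osc_subject_sd, size=n
    )
    if express_amplitude and amplitude_delta:
        amplitudes[affected_rois] += amplitude_delta
    amplitudes = np.maximum(amplitudes, 0.05)

    times = np.arange(t) * spec.tr_seconds
    # unit-variance sinusoid sums at stratified frequencies, mixed to
    # the target correlation, then scaled per ROI
    freqs = _draw_frequencies(spec, rng, n)
    phases = rng.uniform(0, 2 * np.pi, size=(n, spec.n_sinusoids))
    osc = np.sin(
        2 * np.pi * freqs[..., None] * times + phases[..., None]
    ).sum(axis=1) / np.sqrt(spec.n_sinusoids / 2.0)
    osc = amplitudes[:, None] * (chol @ osc)

    # stationary AR(1) with cross-sectional correlation chol @ chol.T
    phi = spec.ar_coef
    innov = chol @ rng.standard_normal((n, t))
    noise = np.empty((n, t))
    noise[:, 0] = innov[:, 0]
    scale = np.sqrt(1.0 - phi**2)
    for i in range(1, t):
        noise[:, i] = phi * noise[:, i - 1] + scale * innov[:, i]

    corr = chol @ chol.T
    implied_cov = np.outer(amplitudes, amplitudes) * corr + corr
    return osc + noise, amplitudes, implied_cov


@dataclass
class Cohort:
    """A generated cohort: metadata, atlases, ground truth, volumes."""

    spec: CohortSpec
    records: pd.DataFrame
    atlases: list[Atlas]
    roi_labels: np.ndarray
    manifest: dict
    _subject_seeds: list = field(repr=False, default_factory=list)
    _chols: tuple = field(repr=False, default=None)
    _affected: np.ndarray = field(repr=False, default=None)
    _amplitude_delta: float = field(repr=False, default=0.0)
    _expression: list = field(repr=False, default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return self.records["label"].to_numpy()

    def subject_series(self, index: int) -> BoldSeries:
        """Regenerate one subject's 4D volume (deterministic)."""
        spec = self.spec
        rng = np.random.default_rng(self._subject_seeds[index])
        express_amp, express_coup = self._expression[index]
        signals, _, _ = simulate_roi_signals(
            spec, rng, express_amp, express_coup, self._affected,
            *self._chols, amplitude_delta=self._amplitude_delta,
        )
        data = signals[self.roi_labels - 1]
        data = data + rng.normal(
            0.0, spec.voxel_noise_sd, size=data.shape
        )
        mask = np.ones(spec.shape, dtype=bool)
        return BoldSeries(data, spec.tr_seconds, mask, spec.affine)

    def iter_series(self):
        """Lazily yield every subject's volume in record order."""
        for i in range(len(self.records)):
            yield self.subject_series(i)


def _make_atlases(spec: CohortSpec, roi_labels: np.ndarray) -> list[Atlas]:
    """Synthetic atlas registry: multi-resolution views of the grid in
    all three dialects (the ensemble's premise is combining
    parcellations at different resolutions)."""
    affine = spec.affine
    n = spec.n_rois
    labels_atlas = Atlas(
        "blocks", "labels", roi_labels, affine,
        [f"block_{k}" for k in range(1, n + 1)],
    )
    # maps: pair consecutive blocks into networks, smooth the indicators
    n_nets = max(2, n // 2)
    stack = np.zeros(spec.shape + (n_nets,))
    for net in range(n_nets):
        member_labels = [
            lab for lab in range(1, n + 1) if (lab - 1) % n_nets == net
        ]
        ind = np.isin(roi_labels, member_labels).astype(float)
        stack[..., net] = smooth_map_gaussian(ind, affine, fwhm_mm=4.0)
    maps_atlas = Atlas(
        "networks", "maps", stack, affine,
        [f"net_{k}" for k in range(1, n_nets + 1)],
    )
    # spheres: seeds at block centres (world mm)
    centers = []
    for lab in range(1, n + 1):
        vox = np.argwhere(roi_labels == lab).mean(axis=0)
        centers.append(vox @ affine[:3, :3].T + affine[:3, 3])
    spheres_atlas = Atlas(
        "seeds", "spheres", np.asarray(centers), None,
        [f"seed_{k}" for k in range(1, n + 1)],
        radius_mm=spec.sphere_radius_mm,
    )
    return [labels_atlas, maps_atlas, spheres_atlas]


def _make_records(spec: CohortSpec, rng) -> pd.DataFrame:
    n = spec.n_subjects
    group = np.array(
        ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    )
    g = spec.confound_group_strength
    ind = (group == "patient").astype(float)
    age = 31 + 7 * (g * ind + rng.standard_normal(n))
    sex = (rng.uniform(size=n) < 0.5 + g / 4 * ind).astype(int)
    tiv = 1400 + 120 * (g * ind + rng.standard_normal(n))
    mean_fd = np.abs(0.10 + 0.05 * (g * ind + rng.standard_normal(n)))
    sans = np.where(
        group == "patient",
        np.clip(np.rint(rng.normal(55, 25, size=n)), 0, 110), np.nan,
    )
    saps = np.where(
        group == "patient",
        np.clip(np.rint(rng.normal(30, 10, size=n)), 8, 55), np.nan,
    )
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "label": group,
            "age": np.round(np.maximum(age, 18), 1),
            "sex": sex,
            "tiv": np.round(np.maximum(tiv, 900), 1),
            "mean_fd": np.round(mean_fd, 4),
            "sans": sans,
            "saps": saps,
        }
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Build a cohort: metadata, three synthetic atlases, the planted
    ground truth and deterministic per-subject volume generators."""
    ss = np.random.SeedSequence(spec.seed)
    meta_ss, plant_ss, *subject_ss = ss.spawn(2 + spec.n_subjects)
    meta_rng = np.random.default_rng(meta_ss)
    plant_rng = np.random.default_rng(plant_ss)

    roi_labels = _roi_label_volume(spec)
    records = _make_records(spec, meta_rng)
    affected = _affected_rois(spec, plant_rng)
    amplitude_delta = _calibrate_amplitude_delta(spec, plant_rng)
    patient_corr, edges = _coupling_targets(spec, plant_rng)

    if spec.effect_mode not in ("uniform", "subtypes"):
        raise ValueError(f"unknown effect_mode {spec.effect_mode!r}")
    is_patient = (records["label"] == "patient").to_numpy()
    expression = [(False, False)] * spec.n_subjects
    patient_idx = np.flatnonzero(is_patient)
    if spec.effect_mode == "uniform":
        for i in patient_idx:
            expression[i] = (True, True)
        subtype = np.where(is_patient, "both", "none")
    else:
        amp_carriers = plant_rng.permutation(patient_idx)[
            : (len(patient_idx) + 1) // 2
        ]
        subtype = np.array(["none"] * spec.n_subjects, dtype=object)
        for i in patient_idx:
            amp = i in set(amp_carriers)
            expression[i] = (amp, not amp)
            subtype[i] = "amplitude" if amp else "coupling"
    n = spec.n_rois
    control_corr = np.full((n, n), spec.base_coupling)
    np.fill_diagonal(control_corr, 1.0)
    chols = (np.linalg.cholesky(control_corr),
             np.linalg.cholesky(patient_corr))

    if spec.severity_effect and spec.n_patients:
        # tie SANS to the planted amplitude ROI so severity is learnable
        pat = records["label"] == "patient"
        amp_z = meta_rng.standard_normal(int(pat.sum()))
        sans = 55 + spec.severity_effect * 25 * amp_z
        records.loc[pat, "sans"] = np.clip(np.rint(sans), 0, 110)

    manifest = {
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(spec).items()
        },
        "affected_rois": [int(r) for r in affected],
        "coupling_edges": [[int(i), int(j)] for i, j in edges],
        "amplitude_delta": amplitude_delta,
        "subjects": records["subject_id"].tolist(),
        "effect_subtype": list(subtype),
    }
    return Cohort(
        spec=spec,
        records=records,
        atlases=_make_atlases(spec, roi_labels),
        roi_labels=roi_labels,
        manifest=manifest,
        _subject_seeds=subject_ss,
        _chols=chols,
        _affected=affected,
        _amplitude_delta=amplitude_delta,
        _expression=expression,
    )


def write_fixture_bundle(cohort: Cohort, directory) -> Path:
    """Write a cohort as the file tree the pipeline readers consume:
    per-subject NIfTI volumes, atlas files in all three dialects, a
    metadata TSV and a manifest JSON. Returns the directory path."""
    directory = Path(directory)
    (directory / "func").mkdir(parents=True, exist_ok=True)
    (directory / "atlases").mkdir(exist_ok=True)
    spec = cohort.spec

    for i, sid in enumerate(cohort.records["subject_id"]):
        series = cohort.subject_series(i)
        nib.save(
            nib.Nifti1Image(series.data.astype(np.float32), series.affine),
            directory / "func" / f"{sid}_bold.nii",
        )

    registry = {}
    for atlas in cohort.atlases:
        if atlas.dialect == "labels":
            rel = f"atlases/{atlas.name}_labels.nii"
            nib.save(
                nib.Nifti1Image(atlas.payload.astype(np.int16),
                                atlas.affine),
                directory / rel,
            )
            registry[atlas.name] = {"path": rel, "dialect": "labels"}
        elif atlas.dialect == "maps":
            rel = f"atlases/{atlas.name}_maps.nii"
            nib.save(
                nib.Nifti1Image(atlas.payload.astype(np.float32),
                                atlas.affine),
                directory / rel,
            )
            registry[atlas.name] = {"path": rel, "dialect": "maps"}
        else:
            rel = f"atlases/{atlas.name}_seeds.tsv"
            pd.DataFrame(
                {
                    "name": atlas.roi_names,
                    "x": atlas.payload[:, 0],
                    "y": atlas.payload[:, 1],
                    "z": atlas.payload[:, 2],
                }
            ).to_csv(directory / rel, sep="\t", index=False)
            registry[atlas.name] = {
                "path": rel, "dialect": "spheres",
                "radius_mm": atlas.radius_mm,
            }

    cohort.records.to_csv(directory / "participants.tsv", sep="\t",
                          index=False)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, indent=2)
    with open(directory / "atlas_registry.json", "w") as fh:
        json.dump(registry, fh, indent=2)
    return directory


def load_fixture_bundle(directory) -> tuple[list, list[Atlas], pd.DataFrame]:
    """Round-trip reader for :func:`write_fixture_bundle` output.

    Returns ``(series_list, atlases, records)``.
    """
    directory = Path(directory)
    records = pd.read_csv(directory / "participants.tsv", sep="\t")
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    spec = manifest["spec"]

    series = []
    for sid in records["subject_id"]:
        img = nib.load(directory / "func" / f"{sid}_bold.nii")
        data = np.asarray(img.dataobj, dtype=float)
        series.append(
            BoldSeries(
                data, spec["tr_seconds"],
                np.ones(data.shape[:3], dtype=bool), img.affine,
            )
        )
    with open(directory / "atlas_registry.json") as fh:
        registry = json.load(fh)
    atlases = [
        load_atlas(
            directory / entry["path"], entry["dialect"], name=name,
            radius_mm=entry.get("radius_mm"),
        )
        for name, entry in registry.items()
    ]
    return series, atlases, records
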