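"""Synthetic DCE-MRI phantom cohorts with known subregion structure.

A phantom study is seven co-registered volumes (pre-contrast "plain" plus
post-contrast phases at 60..360 s) containing an ellipsoidal lesion.  Each
lesion voxel follows one of four kinetic archetypes — washout, plateau,
persistent, or non-enhancing — realized as piecewise-linear time-intensity
multipliers: flat at baseline, linear rise to a peak at the first
post-contrast phase, then a linear per-phase slope.  Only the two
enhancement ratios matter to the downstream voxel classifier, so a
pharmacokinetic model would add nothing the classifier can see.

The archetype field is spatially coherent: a Gaussian random field smoothed
at a configurable correlation length is quantile-thresholded inside the
lesion so the empirical subregion fractions match the requested ones.

The binary outcome label ("high" vs "low" Ki-67) acts on two properties of
high-label lesions: the correlation length of the multiplicative intensity
texture inside the malignant (washout + plateau) subregion is multiplied by
``texture_corr_mult`` (longer-range correlation raises GLCM homogeneity
measures such as Idm), and the lesion's x semi-axis is multiplied by
``elongation_factor`` (stretches the coronal footprint, which drives
Maximum2DDiameterColumn).  Effect sizes are configuration, not claims about
real lesions.  Noise is additive Gaussian on the signal: phantom baselines
sit far above the noise floor, where the Rician distribution is
indistinguishable from Gaussian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, InvalidArchetypeError
from .imaging_io import VolumeGrid, save_volume
from .subregions import NONENHANCING, PERSISTENT, PLATEAU, WASHOUT

logger = logging.getLogger(__name__)

PHASE_TIMES_S = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0, 360.0)

__all__ = [
    "TicArchetype",
    "PhantomSpec",
    "DceStudy",
    "ARCHETYPES",
    "tic_template",
    "generate_study",
    "generate_cohort",
    "write_study",
    "write_cohort",
]


@dataclass(frozen=True)
class TicArchetype:
    """A kinetic-curve archetype.

    ``amplitude`` is the peak enhancement as a fraction of baseline;
    ``post_peak_slope`` is the per-phase change of the enhancement factor
    after the peak (fraction of the peak enhancement per phase);
    ``rise_time_s`` is the time to peak (the first post-contrast phase).
    """

    name: str
    amplitude: float
    post_peak_slope: float
    rise_time_s: float = 60.0


#: Default archetypes.  Amplitudes and slopes are chosen so the noise-free
#: curves satisfy their defining enhancement-ratio inequalities with a
#: comfortable margin (>= 0.02), so moderate noise rarely flips a voxel.
ARCHETYPES: dict[str, TicArchetype] = {
    "washout": TicArchetype("washout", amplitude=0.8, post_peak_slope=-0.09),
    "plateau": TicArchetype("plateau", amplitude=0.7, post_peak_slope=0.0),
    "persistent": TicArchetype("persistent", amplitude=0.6, post_peak_slope=0.09),
    "nonenhancing": TicArchetype("nonenhancing", amplitude=0.3, post_peak_slope=0.0),
}

_ARCHETYPE_CODE = {
    "nonenhancing": NONENHANCING,
    "washout": WASHOUT,
    "plateau": PLATEAU,
    "persistent": PERSISTENT,
}
_CODE_ARCHETYPE = {v: k for k, v in _ARCHETYPE_CODE.items()}


@dataclass
class PhantomSpec:
    """Full description of a phantom cohort.

    Axes are (z, y, x); the default grid is 64x64 in-plane with 48 slices
    of 1.2 mm, i.e. shape (48, 64, 64) at spacing (1.2, 1.0, 1.0) mm.
    ``fractions`` are the target (washout, plateau, persistent) volume
    fractions inside the lesion; the remainder is non-enhancing.
    """

    shape: tuple[int, int, int] = (48, 64, 64)
    spacing: tuple[float, float, float] = (1.2, 1.0, 1.0)
    baseline: float = 500.0
    noise_sigma: float = 5.0
    lesion_center_mm: tuple[float, float, float] | None = None
    lesion_semiaxes_mm: tuple[float, float, float] = (12.0, 14.0, 11.0)
    fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    coherence_length_mm: float = 4.0
    texture_corr_length_mm: float = 2.0
    texture_corr_jitter: float = 0.25
    texture_cv: float = 0.15
    texture_corr_mult: float = 1.5
    elongation_factor: float = 1.1
    size_jitter: float = 0.12
    fraction_jitter: float = 0.05
    amplitude_jitter: float = 0.1
    n_high: int = 81
    n_low: int = 38
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.fractions
        if any(x < 0 for x in f) or sum(f) > 1 + 1e-12:
            raise ValueError("fractions must be nonnegative and sum to <= 1")
        if self.n_high < 1 or self.n_low < 1:
            raise ValueError("cohort sizes must be >= 1")
        extent = [n * s for n, s in zip(self.shape, self.spacing)]
        semi = list(self.lesion_semiaxes_mm)
        semi[2] *= self.elongation_factor  # the high-label lesion must fit too
        # allow for the upper tail of the per-subject size jitter
        head = 1.0 + 2.5 * self.size_jitter
        if any(2 * a * head >= e for a, e in zip(semi, extent)):
            raise GeometryError(
                f"lesion semi-axes {self.lesion_semiaxes_mm} mm (elongated "
                f"and jittered: {tuple(a * head for a in semi)}) do not fit "
                f"the {tuple(extent)} mm grid")


@dataclass
class DceStudy:
    """One subject: plain + post-contrast volumes, VOI, truth, label."""

    volumes: list[VolumeGrid]
    times_s: list[float]
    voi: np.ndarray
    label: str | None = None
    truth: np.ndarray | None = None  # ground-truth subregion codes
    subject_id: str | None = None

    def __post_init__(self) -> None:
        ref = self.volumes[0]
        for v in self.volumes[1:]:
            if not v.same_grid(ref):
                raise ValueError("all volumes must share one grid")
        if len(self.times_s) != len(self.volumes):
            raise ValueError("one acquisition time per volume")
        post = self.times_s[1:]
        if any(b <= a for a, b in zip(post, post[1:])):
            raise ValueError("post-contrast phases must be strictly time-ordered")
        if not np.asarray(self.voi, dtype=bool).any():
            from .errors import DegenerateVOIError
            raise DegenerateVOIError("VOI is empty")


# ---------------------------------------------------------------------------
# Kinetic templates


def tic_template(archetype: TicArchetype | str,
                 times_s: Sequence[float] = PHASE_TIMES_S) -> np.ndarray:
    """Per-phase signal multipliers for an archetype.

    ``m[0] = 1`` at the plain scan; the enhancement rises linearly to
    ``1 + amplitude`` at the first post-contrast phase and then follows the
    per-phase slope.  Multipliers are clipped at a small positive floor.
    """
    if isinstance(archetype, str):
        try:
            archetype = ARCHETYPES[archetype]
        except KeyError:
            raise InvalidArchetypeError(
                f"unknown archetype {archetype!r}; expected one of "
                f"{sorted(ARCHETYPES)}") from None
    if archetype.name not in _ARCHETYPE_CODE:
        raise InvalidArchetypeError(f"unknown archetype name {archetype.name!r}")

    times = np.asarray(times_s, dtype=np.float64)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be sorted ascending")

    a, s = archetype.amplitude, archetype.post_peak_slope
    m = np.empty_like(times)
    rise = archetype.rise_time_s
    for i, t in enumerate(times):
        if t <= 0:
            m[i] = 1.0
        elif t <= rise:
            m[i] = 1.0 + a * t / rise
        else:
            phases_past_peak = (t - rise) / (times[1] - times[0]) if len(times) > 1 else 0
            m[i] = 1.0 + a * (1.0 + s * phases_past_peak)
    m = np.clip(m, 0.05, None)
    _validate_margins(archetype, m)
    return m


MARGIN = 0.02


def _validate_margins(archetype: TicArchetype, m: np.ndarray) -> None:
    """Require the noise-free curve to satisfy its class's enhancement-ratio
    inequalities with margin >= 0.02, so moderate noise rarely flips it."""
    er_first = m[1] / m[0] - 1.0
    er_last = m[-1] / m[1] - 1.0
    name = archetype.name
    ok = True
    if name == "nonenhancing":
        ok = er_first <= 0.5 - MARGIN
    else:
        ok = er_first > 0.5 + MARGIN
        if name == "washout":
            ok = ok and er_last < -0.1 - MARGIN
        elif name == "plateau":
            ok = ok and abs(er_last) <= 0.1 - MARGIN
        elif name == "persistent":
            ok = ok and er_last > 0.1 + MARGIN
    if not ok:
        raise InvalidArchetypeError(
            f"archetype {name!r} violates its enhancement-ratio class "
            f"(ER_first={er_first:.3f}, ER_last={er_last:.3f})")


# ---------------------------------------------------------------------------
# Study generation


def _smooth_field(rng: np.random.Generator, shape, spacing, length_mm) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    w = rng.standard_normal(shape)
    sigma_vox = [max(length_mm / s, 1e-6) for s in spacing]
    f = ndimage.gaussian_filter(w, sigma=sigma_vox, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _lesion_mask(spec: PhantomSpec, label: str,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-subject ellipsoid: mean semi-axes jittered by a common lognormal
    size factor plus smaller per-axis factors, truncated to fit the grid."""
    semi = np.asarray(spec.lesion_semiaxes_mm, dtype=np.float64)
    if label == "high":
        semi[2] *= spec.elongation_factor
    sj = spec.size_jitter
    common = np.exp(np.clip(rng.normal(0.0, sj), -2.5 * sj, 2.5 * sj))
    per_axis = np.exp(np.clip(rng.normal(0.0, sj / 2, 3),
                              -1.25 * sj, 1.25 * sj))
    semi = semi * common * per_axis
    extent = [n * s for n, s in zip(spec.shape, spec.spacing)]
    center = spec.lesion_center_mm or tuple(e / 2 for e in extent)
    coords = np.meshgrid(*[(np.arange(n) + 0.5) * s
                           for n, s in zip(spec.shape, spec.spacing)],
                         indexing="ij")
    q = sum(((c - c0) / a) ** 2 for c, c0, a in zip(coords, center, semi))
    mask = q <= 1.0
    if not mask.any():
        raise GeometryError("lesion ellipsoid contains no voxel centers")
    return mask


def _assign_subregions(rng, spec: PhantomSpec, lesion: np.ndarray) -> np.ndarray:
    """Quantile-threshold a smoothed field inside the lesion so empirical
    subregion fractions match the requested ones."""
    u = _smooth_field(rng, spec.shape, spec.spacing, spec.coherence_length_mm)
    vals = u[lesion]
    order = np.argsort(vals, kind="stable")
    n = vals.size
    f = np.asarray(spec.fractions, dtype=np.float64)
    if spec.fraction_jitter > 0:  # per-subject composition variability
        f = np.clip(f + rng.normal(0.0, spec.fraction_jitter, 3), 0.02, None)
        f *= sum(spec.fractions) / f.sum()  # keep the overall enhancing share
    f_w, f_p, f_per = f
    n_w = int(round(f_w * n))
    n_p = int(round(f_p * n))
    n_per = int(round(f_per * n))
    codes = np.full(n, NONENHANCING, dtype=np.int8)
    codes[order[:n_w]] = WASHOUT
    codes[order[n_w:n_w + n_p]] = PLATEAU
    codes[order[n_w + n_p:n_w + n_p + n_per]] = PERSISTENT
    out = np.zeros(spec.shape, dtype=np.int8)
    out[lesion] = codes
    return out


def generate_study(spec: PhantomSpec, label: str, seed: int) -> DceStudy:
    """Generate one phantom study; identical (spec, label, seed) inputs
    give bit-identical output."""
    if label not in ("high", "low"):
        raise ValueError("label must be 'high' or 'low'")
    rng = np.random.default_rng(seed)
    lesion = _lesion_mask(spec, label, rng)
    truth = _assign_subregions(rng, spec, lesion)

    # Multiplicative intensity texture; longer-correlated inside the
    # malignant subregion of high-label lesions.  A per-subject lognormal
    # jitter on the correlation length provides the between-subject
    # variability that keeps single features from separating perfectly.
    tj = spec.texture_corr_jitter
    ell = spec.texture_corr_length_mm * float(
        np.exp(np.clip(rng.normal(0.0, tj), -2.5 * tj, 2.5 * tj)))
    ell_malig = ell * (spec.texture_corr_mult if label == "high" else 1.0)
    base_field = _smooth_field(rng, spec.shape, spec.spacing, ell)
    malig_field = _smooth_field(rng, spec.shape, spec.spacing, ell_malig)
    malignant = (truth == WASHOUT) | (truth == PLATEAU)
    texture = 1.0 + spec.texture_cv * np.where(malignant, malig_field, base_field)
    texture = np.clip(texture, 0.2, None)

    # Per-voxel amplitude jitter, kept away from the ER_first gate.
    jitter = rng.uniform(-spec.amplitude_jitter, spec.amplitude_jitter, spec.shape)

    base = spec.baseline * texture
    volumes = []
    mults = {code: tic_template(name) for name, code in _ARCHETYPE_CODE.items()}
    amp = {code: ARCHETYPES[name].amplitude for name, code in _ARCHETYPE_CODE.items()}
    for t_idx in range(len(PHASE_TIMES_S)):
        sig = np.empty(spec.shape, dtype=np.float64)
        for code, m in mults.items():
            sel = truth == code
            if not sel.any():
                continue
            # scale the enhancement (m - 1) by the jittered amplitude ratio
            a0 = amp[code]
            a_vox = a0 + (jitter[sel] * a0 if code != NONENHANCING else 0.0)
            sig[sel] = base[sel] * (1.0 + (m[t_idx] - 1.0) * a_vox / a0)
        noise = rng.standard_normal(spec.shape) * spec.noise_sigma
        volumes.append(VolumeGrid(sig + noise, spec.spacing))

    return DceStudy(
        volumes=volumes,
        times_s=list(PHASE_TIMES_S),
        voi=lesion,
        label=label,
        truth=truth,
    )


def generate_cohort(spec: PhantomSpec) -> tuple[list[DceStudy], pd.DataFrame]:
    """Generate ``n_high + n_low`` studies with per-study seeds derived
    deterministically from the master seed; returns the studies and a
    cohort table (subject_id, label)."""
    n = spec.n_high + spec.n_low
    seeds = np.random.SeedSequence(spec.seed).generate_state(n) % (2 ** 31)
    labels = ["high"] * spec.n_high + ["low"] * spec.n_low
    studies, rows = [], []
    for i, (lab, s) in enumerate(zip(labels, seeds)):
        study = generate_study(spec, lab, int(s))
        study.subject_id = f"subj_{i:03d}"
        studies.append(study)
        rows.append({"subject_id": study.subject_id, "label": lab})
    return studies, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk representation


def write_study(study: DceStudy, outdir: str | Path) -> None:
    """Write one study as NIfTI: phase_0..phase_N, voi, truth (if any)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spacing = study.volumes[0].spacing
    for i, vol in enumerate(study.volumes):
        save_volume(vol, outdir / f"phase_{i}.nii.gz")
    save_volume(VolumeGrid(study.voi.astype(np.uint8), spacing),
                outdir / "voi.nii.gz")
    if study.truth is not None:
        save_volume(VolumeGrid(study.truth.astype(np.uint8), spacing),
                    outdir / "truth_subregions.nii.gz")


def write_cohort(studies: list[DceStudy], table: pd.DataFrame,
                 outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for study in studies:
        write_study(study, outdir / study.subject_id)
    table.to_csv(outdir / "cohort.csv", index=False)
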