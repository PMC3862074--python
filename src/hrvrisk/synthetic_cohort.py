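"""Synthetic 24-h NN-interval cohorts with clinical covariates.

No public Holter database carries the low-risk / high-risk ischemic
heart-failure contrast this pipeline targets, so cohorts are simulated.
Each record is an additive model on the beat axis,

    NN_n = m(t_n) + sum_b A_b sin(2 pi f_b t_n + phi_b) + sigma eps_n,

with ``m`` a circadian sinusoid (nocturnal lengthening peaking around
03:00), deterministic oscillators in the VLF (~0.01 Hz), LF (~0.1 Hz)
and HF (~0.25 Hz) bands, and ``eps`` 1/f^beta Gaussian noise from
spectral synthesis, so that the spectral indices and the DFA exponent
alpha1 ~ (beta+1)/2 of the generated series are controlled directly.
Ectopic beats are inserted as annotated short-long couplets at a
configurable rate.  Intervals are clamped to [300, 2000] ms.

Clinical covariates (BMI, LVEF, LVDD, LVSD, NT-proBNP, NYHA class) are
drawn from median/IQR-matched distributions per risk group (log-normal
for NT-proBNP, normal for the rest, Bernoulli for NYHA III), and the
high-risk group's profile differs from the low-risk one by a scalable
contrast (shorter meanNN, weaker LF oscillation, lower beta, higher
ectopy, higher NT-proBNP...); contrast 0 makes both groups exchangeable
for null calibration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import HRVError
from .io_preprocess import NNSeries, Tachogram

__all__ = [
    "OscillatorBand",
    "GroupProfile",
    "SyntheticRecord",
    "LR_PROFILE",
    "HR_PROFILE",
    "fractal_noise",
    "blend_profiles",
    "individualize_profile",
    "generate_nn_record",
    "generate_clinical_covariates",
    "generate_cohort",
    "write_cohort",
]

NN_CLAMP_MS = (300.0, 2000.0)


@dataclass(frozen=True)
class OscillatorBand:
    freq_hz: float
    amp_ms: float


@dataclass(frozen=True)
class GroupProfile:
    """Generating parameters of one risk group."""

    label: str
    mean_nn_ms: float
    circadian_amp_ms: float
    circadian_peak_clock_s: float  # clock time of longest NN intervals
    vlf: OscillatorBand
    lf: OscillatorBand
    hf: OscillatorBand
    beta: float  # 1/f^beta exponent of the fractal noise
    noise_sd_ms: float
    ectopy_rate: float
    # between-subject dispersion of the generating parameters; chosen so
    # the cohort's index spread resembles published group inter-quartile
    # ranges (e.g. meanNN IQR ~180 ms, alpha1 IQR ~0.3)
    mean_nn_subject_sd: float = 120.0
    beta_subject_sd: float = 0.4
    amp_subject_logsd: float = 0.3
    noise_subject_logsd: float = 0.3
    circ_subject_logsd: float = 0.4
    # covariates: (median, sd) normals, log-scale for NT-proBNP
    bmi: tuple = (29.0, 4.45)
    lvef: tuple = (35.0, 10.4)
    lvdd: tuple = (61.0, 8.15)
    lvsd: tuple = (49.0, 11.9)
    log_ntprobnp: tuple = (np.log(70.0), 1.115)
    nyha3_prob: float = 0.145

    def validate(self) -> None:
        if not (0 <= self.beta <= 2):
            raise HRVError("beta must lie in [0, 2]")
        if not (0 <= self.ectopy_rate <= 0.3):
            raise HRVError("ectopy rate must lie in [0, 0.3]")
        for band in (self.vlf, self.lf, self.hf):
            if band.amp_ms < 0:
                raise HRVError("oscillator amplitudes must be non-negative")


#: Survivor (low-risk) group: longer intervals, stronger LF drive,
#: stronger short-range correlations (higher beta -> higher alpha1).
LR_PROFILE = GroupProfile(
    label="IHF_LR",
    mean_nn_ms=860.0,
    circadian_amp_ms=80.0,
    circadian_peak_clock_s=3 * 3600,
    vlf=OscillatorBand(0.01, 25.0),
    lf=OscillatorBand(0.10, 15.0),
    hf=OscillatorBand(0.25, 10.0),
    beta=1.6,
    noise_sd_ms=35.0,
    ectopy_rate=0.02,
)

#: Non-survivor (high-risk) group: shorter intervals, depressed LF,
#: more random short-term dynamics, more ectopy, higher NT-proBNP.
HR_PROFILE = GroupProfile(
    label="IHF_HR",
    mean_nn_ms=816.0,
    circadian_amp_ms=60.0,
    circadian_peak_clock_s=3 * 3600,
    vlf=OscillatorBand(0.01, 18.0),
    lf=OscillatorBand(0.10, 8.0),
    hf=OscillatorBand(0.25, 10.0),
    beta=1.3,
    noise_sd_ms=28.0,
    ectopy_rate=0.05,
    bmi=(27.0, 2.97),
    lvef=(30.0, 7.41),
    lvdd=(65.0, 5.19),
    lvsd=(53.0, 5.19),
    log_ntprobnp=(np.log(184.0), 1.250),
    nyha3_prob=0.457,
)


@dataclass
class SyntheticRecord:
    tachogram: Tachogram  # with ectopy and V annotations, as the pipeline reads it
    nn_clean: NNSeries  # the series before ectopy insertion (ground truth)
    params: GroupProfile
    group: str
    record_id: str = ""


def _lerp(a: float, b: float, s: float) -> float:
    return a + s * (b - a)


def blend_profiles(base: GroupProfile, target: GroupProfile, scale: float) -> GroupProfile:
    """Profile at fractional contrast ``scale`` between two groups.

    Every numeric generating parameter (including the covariate
    distribution parameters) is interpolated linearly; ``scale`` 0
    returns the base's generating process and 1 the full target.  The
    label stays the target's.
    """
    kwargs = {}
    for f in dataclasses.fields(GroupProfile):
        a, b = getattr(base, f.name), getattr(target, f.name)
        if f.name == "label":
            kwargs[f.name] = target.label
        elif isinstance(a, OscillatorBand):
            kwargs[f.name] = OscillatorBand(
                _lerp(a.freq_hz, b.freq_hz, scale), _lerp(a.amp_ms, b.amp_ms, scale)
            )
        elif isinstance(a, tuple):
            kwargs[f.name] = tuple(_lerp(x, y, scale) for x, y in zip(a, b))
        else:
            kwargs[f.name] = _lerp(float(a), float(b), scale)
    return GroupProfile(**kwargs)


def individualize_profile(profile: GroupProfile, rng: np.random.Generator) -> GroupProfile:
    """Draw one subject's generating parameters around the group profile.

    Baseline meanNN is normal, oscillator/noise amplitudes log-normal,
    beta normal (clipped to [0, 2]) and the ectopy rate Gamma-distributed
    (shape 2, mean = group rate, clipped to 0.3), so a tail of records
    naturally violates the 10%-ectopy inclusion rule.
    """
    def logn(scale: float, logsd: float) -> float:
        return float(scale * rng.lognormal(0.0, logsd))

    return dataclasses.replace(
        profile,
        mean_nn_ms=float(np.clip(
            rng.normal(profile.mean_nn_ms, profile.mean_nn_subject_sd), 600, 1100)),
        circadian_amp_ms=logn(profile.circadian_amp_ms, profile.circ_subject_logsd),
        vlf=OscillatorBand(profile.vlf.freq_hz,
                           logn(profile.vlf.amp_ms, profile.amp_subject_logsd)),
        lf=OscillatorBand(profile.lf.freq_hz,
                          logn(profile.lf.amp_ms, profile.amp_subject_logsd)),
        hf=OscillatorBand(profile.hf.freq_hz,
                          logn(profile.hf.amp_ms, profile.amp_subject_logsd)),
        beta=float(np.clip(
            rng.normal(profile.beta, profile.beta_subject_sd), 0.0, 2.0)),
        noise_sd_ms=logn(profile.noise_sd_ms, profile.noise_subject_logsd),
        ectopy_rate=float(np.clip(
            rng.gamma(2.0, profile.ectopy_rate / 2.0), 0.0, 0.3)),
    )


def fractal_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance, zero-mean 1/f^beta Gaussian noise (spectral synthesis)."""
    if n < 2:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_nn_record(
    profile: GroupProfile,
    duration_s: float = 86400.0,
    seed: int | np.random.SeedSequence = 0,
    start_clock: int | None = None,
    record_id: str = "",
) -> SyntheticRecord:
    """Simulate one NN-interval record of the given duration.

    Deterministic per seed.  Modulations are evaluated on the nominal
    beat times ``n * meanNN``; the series is truncated at the first beat
    whose cumulative time reaches ``duration_s``.  Ectopy is inserted as
    short-long couplets (0.6x / 1.4x the local interval) annotated "V".
    """
    if duration_s < 35 * 60:
        raise HRVError("records must span at least 35 min")
    profile.validate()
    rng = np.random.default_rng(seed)
    if start_clock is None:
        # ECG hook-up during the clinic day, never after 15:28
        start_clock = int(rng.integers(8 * 3600, 15 * 3600 + 28 * 60))

    tau = profile.mean_nn_ms / 1000.0
    n = int(np.ceil(duration_s / tau * 1.1)) + 16
    t_apx = np.arange(n) * tau
    clock = start_clock + t_apx
    nn = profile.mean_nn_ms + profile.circadian_amp_ms * np.cos(
        2 * np.pi * (clock - profile.circadian_peak_clock_s) / 86400.0
    )
    for band in (profile.vlf, profile.lf, profile.hf):
        phi = rng.uniform(0, 2 * np.pi)
        nn = nn + band.amp_ms * np.sin(2 * np.pi * band.freq_hz * t_apx + phi)
    nn = nn + profile.noise_sd_ms * fractal_noise(n, profile.beta, rng)
    nn = np.clip(nn, *NN_CLAMP_MS)

    cum = np.cumsum(nn) / 1000.0
    stop = int(np.searchsorted(cum, duration_s)) + 1
    nn = nn[: min(stop, n)]
    clean = NNSeries(nn=nn.copy(), start_clock=start_clock, ectopy_fraction=0.0)

    ann = np.full(len(nn), "N", dtype=object)
    n_couplets = int(round(profile.ectopy_rate * len(nn) / 2.0))
    if n_couplets:
        pos = rng.choice(np.arange(1, len(nn) - 2), size=n_couplets, replace=False)
        for i in pos:
            nn[i] *= 0.6
            nn[i + 1] *= 1.4
            ann[i] = ann[i + 1] = "V"
        nn = np.clip(nn, *NN_CLAMP_MS)
    tg = Tachogram(intervals=nn, annotations=ann.tolist(), start_clock=start_clock)
    return SyntheticRecord(
        tachogram=tg, nn_clean=clean, params=profile, group=profile.label,
        record_id=record_id,
    )


def generate_clinical_covariates(
    group: str,
    n: int,
    seed: int | np.random.SeedSequence = 0,
    profile: GroupProfile | None = None,
) -> pd.DataFrame:
    """Median/IQR-matched covariate table for one risk group."""
    if profile is None:
        profile = {"IHF_LR": LR_PROFILE, "IHF_HR": HR_PROFILE}.get(group)
        if profile is None:
            raise HRVError(f"unknown group {group!r}")
    if n < 1:
        raise HRVError("n must be >= 1")
    rng = np.random.default_rng(seed)
    bmi = np.clip(rng.normal(*profile.bmi, size=n), 15, 50)
    lvef = np.clip(rng.normal(*profile.lvef, size=n), 10, 70)
    lvdd = np.clip(rng.normal(*profile.lvdd, size=n), 35, 90)
    lvsd = np.clip(rng.normal(*profile.lvsd, size=n), 20, 80)
    nt = np.exp(rng.normal(*profile.log_ntprobnp, size=n))
    nyha = np.where(rng.uniform(size=n) < profile.nyha3_prob, 3, 2)
    return pd.DataFrame(
        {
            "group": group,
            "BMI": bmi,
            "LVEF": lvef,
            "LVDD": lvdd,
            "LVSD": lvsd,
            "NT-proBNP": nt,
            "NYHA": nyha,
        }
    )


def generate_cohort(
    n_lr: int = 221,
    n_hr: int = 35,
    contrast: float = 1.0,
    seed: int = 0,
    duration_s: float = 86400.0,
) -> tuple[pd.DataFrame, list[SyntheticRecord]]:
    """Full two-group cohort: covariate table plus one record per patient.

    ``contrast`` scales every LR-vs-HR generating difference (records
    and covariates); 0 makes the high-risk group statistically identical
    to the low-risk group.
    """
    if n_lr < 2 or n_hr < 2:
        raise HRVError("each group needs at least 2 patients")
    hr_profile = blend_profiles(LR_PROFILE, HR_PROFILE, contrast)
    root = np.random.SeedSequence(seed)
    ss_records, ss_cov_lr, ss_cov_hr = root.spawn(3)
    rec_seeds = ss_records.spawn(n_lr + n_hr)
    records: list[SyntheticRecord] = []
    ids = []
    for k in range(n_lr + n_hr):
        group_prof = LR_PROFILE if k < n_lr else hr_profile
        rid = f"{'LR' if k < n_lr else 'HR'}{k:04d}"
        subj_ss, rec_ss = rec_seeds[k].spawn(2)
        prof = individualize_profile(group_prof, np.random.default_rng(subj_ss))
        records.append(
            generate_nn_record(prof, duration_s=duration_s, seed=rec_ss,
                               record_id=rid)
        )
        ids.append(rid)
    cov = pd.concat(
        [
            generate_clinical_covariates("IHF_LR", n_lr, ss_cov_lr),
            generate_clinical_covariates("IHF_HR", n_hr, ss_cov_hr,
                                         profile=hr_profile),
        ],
        ignore_index=True,
    )
    cov.insert(0, "id", ids)
    return cov, records


def write_cohort(cov: pd.DataFrame, records: list[SyntheticRecord], outdir) -> None:
    """Emit tachogram files, the cohort CSV and a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = {}
    for rec in records:
        path = outdir / f"{rec.record_id}.csv"
        sc = rec.tachogram.start_clock
        h, rem = divmod(int(sc), 3600)
        m, s = divmod(rem, 60)
        with open(path, "w") as fh:
            fh.write(f"# start={h:02d}:{m:02d}:{s:02d}\n")
            for v, a in zip(rec.tachogram.intervals, rec.tachogram.annotations):
                fh.write(f"{v:.6g},{a}\n")
        truth[rec.record_id] = dataclasses.asdict(rec.params)
    cov.to_csv(outdir / "cohort.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
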