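"""Synthetic photometry sessions, event schedules and droplet count matrices.

Every generator returns its ground truth alongside the simulated data so
downstream stages can be tested against known answers without any external
dataset.

Signal model for photometry (per channel, at time t):

    F465(t) = B465(t) * (1 + s(t) + m(t)) + e(t)
    F405(t) = B405(t) * (1 + kappa * m(t)) + e'(t)

where ``s`` is a sum of double-exponential calcium transients, ``B`` a
channel-specific bi-exponential bleach envelope, ``m`` a shared low-passed
Gaussian motion artifact with coupling ``kappa`` into the isosbestic
channel, and ``e`` white Gaussian noise. The truth records ``s`` in %dF/F.

Droplet counts are negative-binomial draws around per-population marker
programs, with mitochondrial content, hashtag counts, planted doublets
(summed singlet profiles) and hashtag negatives (zeroed hashtag rows).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.signal
import scipy.sparse

from arcpipe.errors import ConfigurationError
from arcpipe.events import ACCESSIBLE_PARADIGMS, PARADIGMS, EventSchedule
from arcpipe.photometry import PhotometrySession

# --------------------------------------------------------------------------
# photometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhotometryGenConfig:
    """Parameters of a simulated two-channel photometry session.

    Kinetics default to slow population GCaMP6s transients as seen in bulk
    fibre photometry (rise ~0.5 s, decay ~5 s); amplitudes are fractional
    dF/F (0.05 = 5 %dF/F). ``bleach_fractions``/``bleach_taus`` give the
    bi-exponential bleach per channel (default ~20% total loss with time
    constants inside a 10-minute recording). ``motion_coupling_405`` is the
    fraction (kappa) of the motion artifact seen by the isosbestic channel.
    """

    duration: float = 600.0  # s
    sampling_rate: float = 100.0  # Hz
    transient_times: tuple[float, ...] | None = None  # s; explicit placement
    transient_rate: float | None = None  # Hz; Poisson placement if times None
    transient_amplitude: float = 0.05  # fractional dF/F
    rise_tau: float = 0.5  # s
    decay_tau: float = 5.0  # s
    bleach_fractions_465: tuple[float, float] = (0.1, 0.1)
    bleach_taus_465: tuple[float, float] = (100.0, 600.0)  # s
    bleach_fractions_405: tuple[float, float] = (0.1, 0.1)
    bleach_taus_405: tuple[float, float] = (100.0, 600.0)  # s
    motion_sd: float = 0.02  # fractional
    motion_cutoff_hz: float = 2.0
    motion_coupling_405: float = 1.0  # kappa in [0, 1]
    noise_sd: float = 0.005  # fractional, per channel
    baseline_465: float = 100.0  # a.u.
    baseline_405: float = 80.0  # a.u.
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ConfigurationError("duration and sampling_rate must be > 0")
        if not (self.decay_tau > self.rise_tau > 0):
            raise ConfigurationError("need decay_tau > rise_tau > 0")
        if self.baseline_465 <= 0 or self.baseline_405 <= 0:
            raise ConfigurationError("channel baselines must be > 0")
        if not (0.0 <= self.motion_coupling_405 <= 1.0):
            raise ConfigurationError("motion_coupling_405 must be in [0, 1]")
        if self.motion_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("noise magnitudes must be >= 0")
        if self.transient_rate is not None and self.transient_rate < 0:
            raise ConfigurationError("transient_rate must be >= 0")
        for fr in (*self.bleach_fractions_465, *self.bleach_fractions_405):
            if not (0.0 <= fr < 1.0):
                raise ConfigurationError("bleach fractions must be in [0, 1)")


@dataclass
class PhotometryTruth:
    """Ground truth for one simulated session."""

    clean_dff: np.ndarray  # %dF/F; exactly 0 outside kernel support
    transient_times: np.ndarray  # s
    peak_amplitudes: np.ndarray  # %dF/F per transient


def kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Closed-form peak time of ``exp(-t/decay) - exp(-t/rise)``."""
    return (rise_tau * decay_tau / (decay_tau - rise_tau)) * math.log(
        decay_tau / rise_tau
    )


def transient_kernel(
    t: np.ndarray, rise_tau: float, decay_tau: float
) -> np.ndarray:
    """Double-exponential kernel normalised to unit peak; zero for t < 0."""
    tpk = kernel_peak_time(rise_tau, decay_tau)
    height = math.exp(-tpk / decay_tau) - math.exp(-tpk / rise_tau)
    out = np.zeros_like(t, dtype=float)
    pos = t >= 0
    out[pos] = (np.exp(-t[pos] / decay_tau) - np.exp(-t[pos] / rise_tau)) / height
    return out


def _bleach_envelope(
    t: np.ndarray, fractions: Sequence[float], taus: Sequence[float]
) -> np.ndarray:
    env = np.ones_like(t)
    for f, tau in zip(fractions, taus):
        env = env - f * (1.0 - np.exp(-t / tau))
    return env


def _lowpass_motion(
    rng: np.random.Generator, n: int, fs: float, cutoff_hz: float, sd: float
) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if cutoff_hz < fs / 2:
        b, a = scipy.signal.butter(2, cutoff_hz, fs=fs)
        m = scipy.signal.filtfilt(b, a, white)
    else:
        m = white
    s = m.std()
    return m * (sd / s) if s > 0 else m


def simulate_photometry(
    cfg: PhotometryGenConfig,
) -> tuple[PhotometrySession, PhotometryTruth]:
    """Simulate a two-channel session plus its ground-truth %dF/F."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate

    if cfg.transient_times is not None:
        times = np.asarray(cfg.transient_times, dtype=float)
    elif cfg.transient_rate:
        k = rng.poisson(cfg.transient_rate * cfg.duration)
        times = np.sort(rng.uniform(0.0, cfg.duration, size=k))
    else:
        times = np.array([])

    s = np.zeros(n)
    for t0 in times:
        i0 = int(np.searchsorted(t, t0))
        if i0 >= n:
            continue
        s[i0:] += cfg.transient_amplitude * transient_kernel(
            t[i0:] - t0, cfg.rise_tau, cfg.decay_tau
        )

    m = _lowpass_motion(rng, n, cfg.sampling_rate, cfg.motion_cutoff_hz, cfg.motion_sd)
    b465 = cfg.baseline_465 * _bleach_envelope(t, cfg.bleach_fractions_465, cfg.bleach_taus_465)
    b405 = cfg.baseline_405 * _bleach_envelope(t, cfg.bleach_fractions_405, cfg.bleach_taus_405)

    f465 = b465 * (1.0 + s + m)
    f405 = b405 * (1.0 + cfg.motion_coupling_405 * m)
    if cfg.noise_sd > 0:
        f465 = f465 + rng.normal(0.0, cfg.noise_sd * cfg.baseline_465, size=n)
        f405 = f405 + rng.normal(0.0, cfg.noise_sd * cfg.baseline_405, size=n)

    session = PhotometrySession(
        time=t, f465=f465, f405=f405, sampling_rate=cfg.sampling_rate
    )
    truth = PhotometryTruth(
        clean_dff=100.0 * s,
        transient_times=times,
        peak_amplitudes=np.full(len(times), 100.0 * cfg.transient_amplitude),
    )
    return session, truth


# --------------------------------------------------------------------------
# event schedules
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EventGenConfig:
    """Timing parameters for simulated behavioural sessions.

    Eating latency after presentation is ``latency_min + Exp(latency_scale)``
    seconds (mean ``latency_min + latency_scale``), a right-skewed shape
    typical of approach latencies in fasted mice.
    """

    presentation_time: float = 60.0  # s
    latency_min: float = 5.0  # s
    latency_scale: float = 25.0  # s
    removal_delays: Mapping[str, float] = field(
        default_factory=lambda: {"removal_2min": 120.0, "removal_10min": 600.0}
    )


def simulate_event_schedule(
    paradigm: str, seed: int, cfg: EventGenConfig | None = None
) -> EventSchedule:
    """Generate a presentation/eating/removal schedule for one paradigm.

    Accessible-food paradigms get an eating onset strictly after
    presentation; removal paradigms place the removal at presentation +120 s
    or +600 s, with the eating onset resampled to precede the removal.
    """
    if paradigm not in PARADIGMS:
        raise ConfigurationError(f"unknown paradigm {paradigm!r}; known: {PARADIGMS}")
    cfg = cfg or EventGenConfig()
    rng = np.random.default_rng(seed)
    events: list[tuple[float, str]] = [(cfg.presentation_time, "presentation")]

    if paradigm in ACCESSIBLE_PARADIGMS:
        limit = cfg.removal_delays.get(paradigm, math.inf)
        latency = cfg.latency_min + rng.exponential(cfg.latency_scale)
        while latency >= limit:  # the mouse must reach the food before removal
            latency = cfg.latency_min + rng.exponential(cfg.latency_scale)
        events.append((cfg.presentation_time + latency, "eating_onset"))

    if paradigm in cfg.removal_delays:
        events.append(
            (cfg.presentation_time + cfg.removal_delays[paradigm], "removal")
        )

    events.sort(key=lambda e: e[0])
    return EventSchedule(events=tuple(events), paradigm=paradigm)


# --------------------------------------------------------------------------
# droplet counts
# --------------------------------------------------------------------------

#: Genes scored as neuronal identity markers in every simulated cell.
NEURONAL_MARKERS = ("Tubb3", "Snap25", "Syt1", "Elavl4")

#: Default mitochondrial gene names (screen identifies them by prefix).
MITO_GENES = ("mt-Nd1", "mt-Co1", "mt-Cytb")


def default_marker_programs() -> dict[str, dict[str, float]]:
    """Marker programs for the planted ARC populations.

    Mean counts per cell for population-defining genes; all other genes sit
    at the background mean. The Bnc2 population co-expresses Lepr and the
    GABAergic program (Slc32a1/Gad1/Gad2) and lacks Agrp/Npy/Pomc; the
    Nr5a1 population is the Lepr-positive ventromedial-hypothalamus
    confound that the candidate screen must exclude.
    """
    return {
        "Agrp_Npy": {"Agrp": 8.0, "Npy": 8.0, "Lepr": 4.0,
                     "Slc32a1": 4.0, "Gad1": 3.0, "Gad2": 3.0},
        "Pomc": {"Pomc": 8.0, "Lepr": 1.5, "Slc17a6": 3.0},
        "Bnc2_Lepr": {"Bnc2": 6.0, "Lepr": 4.0,
                      "Slc32a1": 4.0, "Gad1": 2.0, "Gad2": 2.0},
        "Nr5a1": {"Nr5a1": 8.0, "Lepr": 3.0, "Slc17a6": 4.0},
        "Other": {"Ghrh": 5.0, "Slc17a6": 3.0},
    }


def default_population_sizes() -> dict[str, int]:
    return {"Agrp_Npy": 600, "Pomc": 300, "Bnc2_Lepr": 100, "Nr5a1": 200, "Other": 800}


@dataclass(frozen=True)
class CountsGenConfig:
    """Parameters of a simulated droplet count matrix with hashtags.

    The default panel pads the marker genes with 1,500 filler genes at mean
    2 counts/cell, giving ~1,100 detected features and ~3,000 total counts
    per cell — inside the 800-5,000 feature and 12,000-count QC window a
    real nuclear droplet library occupies.
    """

    n_cells: Mapping[str, int] = field(default_factory=default_population_sizes)
    marker_programs: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_marker_programs
    )
    gene_panel: tuple[str, ...] | None = None  # default: programs + markers + filler
    n_filler_genes: int = 1500
    filler_mean: float = 2.0
    background_mean: float = 0.02
    neuronal_marker_mean: float = 3.0
    dispersion: float = 2.0  # NB size parameter r (var = mu + mu^2/r)
    mito_fraction_alpha: float = 2.0  # Beta(alpha, beta) target mito fraction
    mito_fraction_beta: float = 398.0  # mean 0.005
    n_hashtags: int = 4
    hto_signal_mean: float = 200.0
    hto_background_mean: float = 10.0
    doublet_rate: float = 0.05
    negative_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for rate in (self.doublet_rate, self.negative_rate):
            if not (0.0 <= rate <= 1.0):
                raise ConfigurationError("rates must be in [0, 1]")
        if any(n < 0 for n in self.n_cells.values()):
            raise ConfigurationError("population sizes must be >= 0")
        if not set(self.n_cells) <= set(self.marker_programs):
            raise ConfigurationError(
                "every population in n_cells needs a marker program"
            )
        if self.n_hashtags < 1:
            raise ConfigurationError("need at least one hashtag")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")

    def resolved_panel(self) -> tuple[str, ...]:
        """Gene panel: program genes, classifiers, neuronal and mito markers,
        then filler genes that give cells realistic totals."""
        if self.gene_panel is not None:
            if len(self.gene_panel) == 0:
                raise ConfigurationError("gene panel is empty")
            return tuple(self.gene_panel)
        genes: list[str] = []
        for prog in self.marker_programs.values():
            for g in prog:
                if g not in genes:
                    genes.append(g)
        for g in ("Agrp", "Npy", "Pomc", "Bnc2", "Lepr", "Nr5a1",
                  "Slc17a6", "Slc32a1", "Gad1", "Gad2"):
            if g not in genes:
                genes.append(g)
        genes.extend(m for m in NEURONAL_MARKERS if m not in genes)
        genes.extend(f"Filler{i:03d}" for i in range(self.n_filler_genes))
        genes.extend(MITO_GENES)
        return tuple(genes)


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, size_param: float
) -> np.ndarray:
    """Negative binomial with mean ``mean`` and size (dispersion) ``r``."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = size_param / (size_param + mean[pos])
    out[pos] = rng.negative_binomial(size_param, p)
    return out


def nb_tail_probability(mean: float, size_param: float, min_count: int) -> float:
    """P(X >= min_count) for NB(mean mu, size r) — analytic call-rate oracle."""
    from scipy.stats import nbinom

    p = size_param / (size_param + mean)
    return float(nbinom.sf(min_count - 1, size_param, p))


def simulate_counts(cfg: CountsGenConfig) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate a cell x gene count matrix with hashtags and ground truth.

    Returns an :class:`anndata.AnnData` (integer ``X``, hashtag counts in
    ``obsm["hto"]``) and a per-barcode truth table (population, hashtag,
    doublet flag, target mito fraction).
    """
    cfg.validate()
    genes = cfg.resolved_panel()
    rng = np.random.default_rng(cfg.seed)
    gene_idx = {g: i for i, g in enumerate(genes)}
    mito_idx = [i for i, g in enumerate(genes) if g.lower().startswith("mt-")]
    filler_idx = [i for i, g in enumerate(genes) if g.startswith("Filler")]
    neuronal_idx = [gene_idx[g] for g in NEURONAL_MARKERS if g in gene_idx]

    # per-population mean vectors over the non-mito panel
    pop_names = list(cfg.n_cells)
    base_mean = np.full(len(genes), cfg.background_mean)
    base_mean[filler_idx] = cfg.filler_mean
    base_mean[neuronal_idx] = cfg.neuronal_marker_mean
    base_mean[mito_idx] = 0.0  # mito added separately to hit target fractions
    pop_means = {}
    for pop in pop_names:
        mu = base_mean.copy()
        for g, m in cfg.marker_programs[pop].items():
            mu[gene_idx[g]] = m
        pop_means[pop] = mu

    n_total = int(sum(cfg.n_cells.values()))
    X = np.zeros((n_total, len(genes)), dtype=np.int64)
    pop_labels = np.empty(n_total, dtype=object)
    row = 0
    for pop in pop_names:
        k = cfg.n_cells[pop]
        if k:
            X[row : row + k] = _nb_draw(
                rng, np.broadcast_to(pop_means[pop], (k, len(genes))), cfg.dispersion
            )
            pop_labels[row : row + k] = pop
        row += k

    # mitochondrial content: draw a target fraction, add matching mt- counts
    mito_frac = rng.beta(cfg.mito_fraction_alpha, cfg.mito_fraction_beta, size=n_total)
    if mito_idx:
        rest = X.sum(axis=1)
        mito_total = np.round(rest * mito_frac / (1.0 - mito_frac)).astype(np.int64)
        probs = np.full(len(mito_idx), 1.0 / len(mito_idx))
        for i in range(n_total):
            if mito_total[i] > 0:
                X[i, mito_idx] = rng.multinomial(mito_total[i], probs)

    # hashtags
    hashtags = np.array([f"HTO{h+1}" for h in range(cfg.n_hashtags)])
    hto_id = rng.integers(cfg.n_hashtags, size=n_total)
    hto_mean = np.full((n_total, cfg.n_hashtags), cfg.hto_background_mean)
    hto_mean[np.arange(n_total), hto_id] = cfg.hto_signal_mean
    hto = _nb_draw(rng, hto_mean, cfg.dispersion)
    hto_labels = hashtags[hto_id].astype(object)

    # hashtag negatives: zero the hashtag counts of a sampled subset
    n_neg = int(round(cfg.negative_rate * n_total))
    neg_rows = rng.choice(n_total, size=n_neg, replace=False) if n_neg else np.array([], dtype=int)
    hto[neg_rows] = 0
    hto_labels[neg_rows] = "negative"

    # doublets: merge sampled singlet pairs by summing their counts
    n_dbl = int(round(cfg.doublet_rate * n_total))
    doublet_flag = np.zeros(n_total, dtype=bool)
    primary_labels = pop_labels.copy()  # dominant component of each barcode
    if 2 * n_dbl > n_total:
        raise ConfigurationError("doublet_rate too high for the population size")
    if n_dbl:
        pair_rows = rng.choice(n_total, size=2 * n_dbl, replace=False)
        a_rows, b_rows = pair_rows[:n_dbl], pair_rows[n_dbl:]
        for a, b in zip(a_rows, b_rows):
            # a clustering stage would place the merged profile with its
            # larger component, so that is the "primary" truth label
            primary_labels[a] = pop_labels[a if X[a].sum() >= X[b].sum() else b]
            pop_labels[a] = f"{pop_labels[a]}+{pop_labels[b]}"
            if hto_labels[a] != hto_labels[b]:
                hto_labels[a] = "mixed"
        X[a_rows] += X[b_rows]
        hto[a_rows] += hto[b_rows]
        doublet_flag[a_rows] = True
        keep = np.setdiff1d(np.arange(n_total), b_rows)
        X, hto = X[keep], hto[keep]
        pop_labels, hto_labels = pop_labels[keep], hto_labels[keep]
        doublet_flag, mito_frac = doublet_flag[keep], mito_frac[keep]
        primary_labels = primary_labels[keep]

    barcodes = [f"CELL{i:05d}" for i in range(X.shape[0])]
    truth = pd.DataFrame(
        {
            "population": pop_labels,
            "primary_population": primary_labels,
            "hashtag": hto_labels,
            "is_doublet": doublet_flag,
            "target_mito_fraction": mito_frac,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    adata = ad.AnnData(
        X=X.astype(np.int32),
        obs=truth.copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.obsm["hto"] = pd.DataFrame(hto, index=adata.obs_names, columns=hashtags)
    return adata, truth


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------


def write_session_csv(session: PhotometrySession, path: str | Path) -> None:
    session.to_frame().to_csv(path, index=False)


def write_session_hdf5(session: PhotometrySession, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time_s", data=session.time)
        f.create_dataset("f465", data=session.f465)
        f.create_dataset("f405", data=session.f405)
        f.attrs["sampling_rate"] = session.sampling_rate


def read_session_csv(path: str | Path, sampling_rate: float | None = None) -> PhotometrySession:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = sampling_rate or 1.0 / float(np.median(np.diff(t)))
    return PhotometrySession(time=t, f465=df["f465"].to_numpy(),
                             f405=df["f405"].to_numpy(), sampling_rate=fs)


def read_session_hdf5(path: str | Path) -> PhotometrySession:
    with h5py.File(path, "r") as f:
        return PhotometrySession(
            time=f["time_s"][:], f465=f["f465"][:], f405=f["f405"][:],
            sampling_rate=float(f.attrs["sampling_rate"]),
        )


def write_events_csv(schedule: EventSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def write_counts_mtx(
    adata: ad.AnnData, truth: pd.DataFrame, outdir: str | Path, seed: int | None = None
) -> None:
    """MatrixMarket MTX (genes x cells, 10x convention) + features/barcodes/
    hashtag/truth TSVs, with a JSON seed sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = scipy.sparse.csr_matrix(X).T  # genes x cells
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    if "hto" in adata.obsm:
        adata.obsm["hto"].to_csv(outdir / "hto_counts.tsv", sep="\t")
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    if seed is not None:
        (outdir / "provenance.json").write_text(json.dumps({"seed": seed}) + "\n")


def read_counts_mtx(outdir: str | Path) -> ad.AnnData:
    outdir = Path(outdir)
    mat = scipy.io.mmread(str(outdir / "matrix.mtx")).tocsr().T.tocsr()
    genes = pd.read_csv(outdir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(outdir / "barcodes.tsv", sep="\t", header=None)[0]
    adata = ad.AnnData(
        X=np.asarray(mat.todense(), dtype=np.int32),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    hto_path = outdir / "hto_counts.tsv"
    if hto_path.exists():
        adata.obsm["hto"] = pd.read_csv(hto_path, sep="\t", index_col=0)
    return adata
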