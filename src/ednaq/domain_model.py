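"""Core data structures for qPCR CT surveys.

A survey consists of ``n`` sites visited at ``T`` occasions; at occasion
``(i, t)`` a number ``M[i, t]`` of environmental samples is collected, each
analysed in ``K[i, t, m]`` PCR technical replicates on a single plate.
Replicates either report a cycle-threshold (CT) value or fail to amplify
within ``ct_max`` cycles, in which case they are right-censored.  Each plate
also carries standards of known concentration used to calibrate the
CT-vs-log-concentration line.

Censoring is represented by an explicit flag (``ct is None`` on observations,
a boolean mask on array containers) rather than a numeric sentinel.
On-disk CSV files use 1-based indices; in memory everything is 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CENSORED",
    "SurveyDesign",
    "CovariateSet",
    "CTObservation",
    "StandardsSet",
    "ModelParameters",
    "LatentState",
    "SurveyDataset",
    "validate_dataset",
    "assemble_dataset",
    "read_dataset",
    "write_dataset",
]

#: Marker used for censored CT values in scalar contexts.
CENSORED = None


@dataclass(frozen=True)
class SurveyDesign:
    """Layout of a survey: who was sampled, when, and on which plate.

    Parameters
    ----------
    n_sites, n_times
        Number of sites ``n`` and sampling occasions ``T``.
    samples_per_occasion
        Integer array of shape ``(n, T)``; entry ``M[i, t] >= 1``.
    replicates_per_sample
        Integer array of shape ``(n, T, max_M)``; entry ``K[i, t, m]`` is
        the replicate count for sample ``m`` (only ``m < M[i, t]`` is used).
    plate_of_occasion
        Integer array of shape ``(n, T)`` mapping each occasion to the
        (0-based) plate on which all its replicates are analysed.
    ct_max
        Maximum cycle number; replicates not amplifying by then are censored.
    """

    n_sites: int
    n_times: int
    samples_per_occasion: np.ndarray
    replicates_per_sample: np.ndarray
    plate_of_occasion: np.ndarray
    ct_max: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples_per_occasion",
            np.asarray(self.samples_per_occasion, dtype=int))
        object.__setattr__(
            self, "replicates_per_sample",
            np.asarray(self.replicates_per_sample, dtype=int))
        object.__setattr__(
            self, "plate_of_occasion",
            np.asarray(self.plate_of_occasion, dtype=int))

    @property
    def n_plates(self) -> int:
        return int(self.plate_of_occasion.max()) + 1

    @property
    def max_samples(self) -> int:
        return int(self.samples_per_occasion.max())

    def n_replicate_rows(self) -> int:
        """Total number of environmental replicate observations implied."""
        total = 0
        for i in range(self.n_sites):
            for t in range(self.n_times):
                for m in range(self.samples_per_occasion[i, t]):
                    total += int(self.replicates_per_sample[i, t, m])
        return total

    @staticmethod
    def rectangular(n_sites: int, n_times: int, M: int, K: int,
                    ct_max: float = 40.0,
                    plate_of_occasion: Optional[np.ndarray] = None,
                    ) -> "SurveyDesign":
        """Balanced design: M samples and K replicates everywhere.

        By default every occasion is analysed on its own distinct plate.
        """
        Mm = np.full((n_sites, n_times), M, dtype=int)
        Kk = np.full((n_sites, n_times, M), K, dtype=int)
        if plate_of_occasion is None:
            plate_of_occasion = np.arange(n_sites * n_times).reshape(
                n_sites, n_times)
        return SurveyDesign(n_sites, n_times, Mm, Kk,
                            np.asarray(plate_of_occasion), float(ct_max))


@dataclass(frozen=True)
class CovariateSet:
    """Site-level and sample-level covariates.

    ``site`` has shape ``(n, T, q_b)``; ``sample`` has shape
    ``(n, T, max_M, q_w)``.  Missing values are not supported.
    """

    site: np.ndarray
    sample: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", np.asarray(self.site, dtype=float))
        object.__setattr__(self, "sample",
                           np.asarray(self.sample, dtype=float))

    @property
    def n_site_covariates(self) -> int:
        return self.site.shape[-1]

    @property
    def n_sample_covariates(self) -> int:
        return self.sample.shape[-1]


@dataclass(frozen=True)
class CTObservation:
    """One PCR replicate: indices plus its CT value (``None`` = censored)."""

    site: int
    time: int
    sample: int
    replicate: int
    plate: int
    ct: Optional[float]

    @property
    def is_censored(self) -> bool:
        return self.ct is None


@dataclass(frozen=True)
class StandardsSet:
    """Standards of known concentration analysed alongside samples.

    Arrays are aligned by standard index: ``concentration[s] > 0`` is the
    known amount ``w*_s``, ``ct[s]`` its observed CT (NaN where
    ``censored[s]`` is True; the flag, not the NaN, is authoritative) and
    ``plate[s]`` the 0-based plate.
    """

    plate: np.ndarray
    concentration: np.ndarray
    ct: np.ndarray
    censored: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "plate", np.asarray(self.plate, dtype=int))
        object.__setattr__(self, "concentration",
                           np.asarray(self.concentration, dtype=float))
        object.__setattr__(self, "ct", np.asarray(self.ct, dtype=float))
        object.__setattr__(self, "censored",
                           np.asarray(self.censored, dtype=bool))

    def __len__(self) -> int:
        return self.plate.shape[0]


@dataclass
class ModelParameters:
    """Every top-level unknown of the model plus the fixed constants.

    ``alpha1``/``alpha2`` are per-plate CT regression intercepts/slopes;
    ``a1``/``a2`` regress log CT-variance on log concentration; ``p_c`` and
    ``p_h`` are the contamination/inhibition probabilities, constrained so
    that ``p_c + p_h < 0.5``.  ``sigma_c`` (contaminated/inhibited CT sd)
    and ``ct_max`` are fixed, not estimated.
    """

    beta_b0: float
    beta_b: np.ndarray
    beta_w: np.ndarray
    rho: np.ndarray
    rho0: float
    sigma2_rho: float
    tau2: float
    tau2_1: float
    sigma2: float
    alpha1: np.ndarray
    alpha2: np.ndarray
    alpha1_0: float
    alpha2_0: float
    sigma2_alpha: float
    a1: float
    a2: float
    p_c: float
    p_h: float
    sigma_c: float
    ct_max: float
    sigma2_P: Optional[float] = None  # constant-CT-variance variant only

    def __post_init__(self) -> None:
        self.beta_b = np.atleast_1d(np.asarray(self.beta_b, dtype=float))
        self.beta_w = np.atleast_1d(np.asarray(self.beta_w, dtype=float))
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        self.alpha1 = np.atleast_1d(np.asarray(self.alpha1, dtype=float))
        self.alpha2 = np.atleast_1d(np.asarray(self.alpha2, dtype=float))

    def probability_constraint_ok(self) -> bool:
        """p_c + p_h must stay below 1 - (p_c + p_h)."""
        return (self.p_c >= 0.0 and self.p_h >= 0.0
                and self.p_c + self.p_h < 0.5)

    def violations(self) -> list[str]:
        out = []
        if not self.probability_constraint_ok():
            out.append(
                f"probability constraint violated: p_c={self.p_c}, "
                f"p_h={self.p_h} (need p_c+p_h < 0.5, both >= 0)")
        for name in ("sigma2_rho", "tau2", "tau2_1", "sigma2",
                     "sigma2_alpha", "sigma_c", "ct_max"):
            if not getattr(self, name) > 0:
                out.append(f"{name} must be > 0")
        if self.sigma2_P is not None and not self.sigma2_P > 0:
            out.append("sigma2_P must be > 0")
        return out


@dataclass
class LatentState:
    """Latent quantities: availability ``l[i, t]``, per-sample log-DNA
    ``v[i, t, m]`` and replicate status ``gamma[i, t, m, k]`` (0 = clean,
    1 = contaminated, 2 = inhibited)."""

    l: np.ndarray
    v: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=int)


@dataclass
class SurveyDataset:
    """All observed quantities: design, covariates, CT table, standards."""

    design: SurveyDesign
    covariates: CovariateSet
    observations: list[CTObservation]
    standards: StandardsSet

    def ct_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense ``(n, T, max_M, max_K)`` views of the CT table.

        Returns ``(ct, censored, valid)`` where ``ct`` is NaN outside
        ``valid`` and on censored cells.
        """
        d = self.design
        max_K = max((int(k) for k in d.replicates_per_sample.ravel()),
                    default=1)
        shape = (d.n_sites, d.n_times, d.max_samples, max_K)
        ct = np.full(shape, np.nan)
        cens = np.zeros(shape, dtype=bool)
        valid = np.zeros(shape, dtype=bool)
        for o in self.observations:
            idx = (o.site, o.time, o.sample, o.replicate)
            valid[idx] = True
            if o.is_censored:
                cens[idx] = True
            else:
                ct[idx] = o.ct
        return ct, cens, valid


def validate_dataset(dataset: SurveyDataset) -> list[str]:
    """Check every structural invariant; return the list of violations.

    An empty list means the dataset is valid.  Violations are reported with
    index coordinates rather than raised.
    """
    report: list[str] = []
    d = dataset.design
    if d.n_sites < 1 or d.n_times < 1:
        report.append("design: n_sites and n_times must be >= 1")
    if not d.ct_max > 0:
        report.append("design: ct_max must be > 0")
    if d.samples_per_occasion.shape != (d.n_sites, d.n_times):
        report.append("design: samples_per_occasion has wrong shape")
        return report
    if (d.samples_per_occasion < 1).any():
        report.append("design: all M[i,t] must be >= 1")
    for i in range(d.n_sites):
        for t in range(d.n_times):
            for m in range(d.samples_per_occasion[i, t]):
                if d.replicates_per_sample[i, t, m] < 1:
                    report.append(
                        f"design: K[{i},{t},{m}] must be >= 1")
    if (d.plate_of_occasion < 0).any():
        report.append("design: plate indices must be non-negative")

    cov = dataset.covariates
    if cov.site.shape[:2] != (d.n_sites, d.n_times):
        report.append("covariates: site array shape inconsistent with design")
    if cov.sample.shape[:3] != (d.n_sites, d.n_times, d.max_samples):
        report.append(
            "covariates: sample array shape inconsistent with design")
    if not np.isfinite(cov.site).all() or not np.isfinite(cov.sample).all():
        report.append("covariates: missing/non-finite values not allowed")

    expected = set()
    for i in range(d.n_sites):
        for t in range(d.n_times):
            for m in range(d.samples_per_occasion[i, t]):
                for k in range(d.replicates_per_sample[i, t, m]):
                    expected.add((i, t, m, k))
    seen = set()
    for o in dataset.observations:
        key = (o.site, o.time, o.sample, o.replicate)
        if key in seen:
            report.append(f"observations: duplicate cell {key}")
        seen.add(key)
        if key not in expected:
            report.append(f"observations: cell {key} not implied by design")
            continue
        if o.plate != d.plate_of_occasion[o.site, o.time]:
            report.append(
                f"observations: cell {key} on plate {o.plate} but occasion "
                f"({o.site},{o.time}) maps to plate "
                f"{d.plate_of_occasion[o.site, o.time]}")
        if not o.is_censored and not (0.0 < o.ct < d.ct_max):
            report.append(
                f"observations: cell {key} has ct={o.ct} outside "
                f"(0, {d.ct_max})")
    missing = expected - seen
    for key in sorted(missing):
        report.append(f"observations: cell {key} missing")

    s = dataset.standards
    if (s.concentration <= 0).any():
        bad = np.nonzero(s.concentration <= 0)[0]
        report.append(f"standards: non-positive concentration at rows "
                      f"{bad.tolist()}")
    if ((s.plate < 0) | (s.plate >= d.n_plates)).any():
        report.append("standards: plate index outside {0..P-1}")
    obs_std = ~s.censored
    if obs_std.any():
        ok = (s.ct[obs_std] > 0) & (s.ct[obs_std] < d.ct_max)
        if not ok.all():
            report.append("standards: observed ct outside (0, ct_max)")

    return report


# ---------------------------------------------------------------------------
# CSV assembly / round trip.  File dialect: 1-based indices, empty ct cell
# (or literal "NA") means censored.
# ---------------------------------------------------------------------------

def _censored_from_cell(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and np.isnan(x):
        return True
    if isinstance(x, str) and x.strip() in ("", "NA", "NaN", "nan"):
        return True
    return False


def assemble_dataset(ct_table: pd.DataFrame,
                     site_covariates: pd.DataFrame,
                     sample_covariates: pd.DataFrame,
                     standards_table: pd.DataFrame,
                     design_spec: dict) -> SurveyDataset:
    """Build a validated :class:`SurveyDataset` from tabular inputs.

    ``design_spec`` must provide ``n_sites``, ``n_times`` and ``ct_max``;
    the sampling layout (M, K, plate map) is read off the replicate table.
    Raises ``ValueError`` on malformed tables or invariant violations.
    """
    n = int(design_spec["n_sites"])
    T = int(design_spec["n_times"])
    ct_max = float(design_spec["ct_max"])

    req = {"site", "time", "sample", "replicate", "plate", "ct"}
    if not req.issubset(ct_table.columns):
        raise ValueError(f"replicate table must have columns {sorted(req)}")

    grp = ct_table.groupby(["site", "time"])
    M = np.zeros((n, T), dtype=int)
    plate_map = np.zeros((n, T), dtype=int)
    for (si, ti), g in grp:
        i, t = int(si) - 1, int(ti) - 1
        M[i, t] = g["sample"].max()
        plates = g["plate"].unique()
        if len(plates) != 1:
            raise ValueError(
                f"occasion (site={si}, time={ti}) spans plates "
                f"{sorted(plates)}; exactly one plate per occasion required")
        plate_map[i, t] = int(plates[0]) - 1
    if (M < 1).any():
        raise ValueError("every (site, time) needs at least one sample")
    max_M = int(M.max())
    K = np.zeros((n, T, max_M), dtype=int)
    for (si, ti, mi), g in ct_table.groupby(["site", "time", "sample"]):
        K[int(si) - 1, int(ti) - 1, int(mi) - 1] = g["replicate"].max()

    design = SurveyDesign(n, T, M, K, plate_map, ct_max)

    cov_cols_b = [c for c in site_covariates.columns
                  if c not in ("site", "time")]
    Xb = np.zeros((n, T, len(cov_cols_b)))
    for _, row in site_covariates.iterrows():
        Xb[int(row["site"]) - 1, int(row["time"]) - 1, :] = \
            row[cov_cols_b].to_numpy(dtype=float)
    cov_cols_w = [c for c in sample_covariates.columns
                  if c not in ("site", "time", "sample")]
    Xw = np.zeros((n, T, max_M, len(cov_cols_w)))
    for _, row in sample_covariates.iterrows():
        Xw[int(row["site"]) - 1, int(row["time"]) - 1,
           int(row["sample"]) - 1, :] = row[cov_cols_w].to_numpy(dtype=float)
    covariates = CovariateSet(Xb, Xw)

    observations = []
    for _, row in ct_table.iterrows():
        raw = row["ct"]
        ct = None if _censored_from_cell(raw) else float(raw)
        observations.append(CTObservation(
            site=int(row["site"]) - 1, time=int(row["time"]) - 1,
            sample=int(row["sample"]) - 1,
            replicate=int(row["replicate"]) - 1,
            plate=int(row["plate"]) - 1, ct=ct))

    sreq = {"plate", "standard_id", "concentration", "ct"}
    if not sreq.issubset(standards_table.columns):
        raise ValueError(f"standards table must have columns {sorted(sreq)}")
    cens = standards_table["ct"].map(_censored_from_cell).to_numpy(bool)
    ct_vals = np.where(
        cens, np.nan,
        pd.to_numeric(standards_table["ct"], errors="coerce").to_numpy())
    standards = StandardsSet(
        plate=standards_table["plate"].to_numpy(int) - 1,
        concentration=standards_table["concentration"].to_numpy(float),
        ct=ct_vals, censored=cens)

    dataset = SurveyDataset(design, covariates, observations, standards)
    problems = validate_dataset(dataset)
    if problems:
        raise ValueError("dataset failed validation:\n  "
                         + "\n  ".join(problems))
    return dataset


def write_dataset(dataset: SurveyDataset, outdir) -> None:
    """Write the four CSV tables plus a design config JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = dataset.design

    rows = []
    for o in sorted(dataset.observations,
                    key=lambda o: (o.site, o.time, o.sample, o.replicate)):
        rows.append({"site": o.site + 1, "time": o.time + 1,
                     "sample": o.sample + 1, "replicate": o.replicate + 1,
                     "plate": o.plate + 1,
                     "ct": "" if o.is_censored else repr(o.ct)})
    pd.DataFrame(rows).to_csv(outdir / "replicates.csv", index=False)

    cov = dataset.covariates
    b_rows = []
    for i in range(d.n_sites):
        for t in range(d.n_times):
            row = {"site": i + 1, "time": t + 1}
            for q in range(cov.n_site_covariates):
                row[f"xb{q + 1}"] = cov.site[i, t, q]
            b_rows.append(row)
    pd.DataFrame(b_rows).to_csv(outdir / "site_covariates.csv", index=False)

    w_rows = []
    for i in range(d.n_sites):
        for t in range(d.n_times):
            for m in range(d.samples_per_occasion[i, t]):
                row = {"site": i + 1, "time": t + 1, "sample": m + 1}
                for q in range(cov.n_sample_covariates):
                    row[f"xw{q + 1}"] = cov.sample[i, t, m, q]
                w_rows.append(row)
    pd.DataFrame(w_rows).to_csv(outdir / "sample_covariates.csv", index=False)

    s = dataset.standards
    s_rows = []
    for j in range(len(s)):
        s_rows.append({
            "plate": int(s.plate[j]) + 1, "standard_id": j + 1,
            "concentration": repr(float(s.concentration[j])),
            "ct": "" if s.censored[j] else repr(float(s.ct[j]))})
    pd.DataFrame(s_rows).to_csv(outdir / "standards.csv", index=False)

    with open(outdir / "design.json", "w") as fh:
        json.dump({"n_sites": d.n_sites, "n_times": d.n_times,
                   "ct_max": d.ct_max}, fh, indent=2)


def read_dataset(indir) -> SurveyDataset:
    """Inverse of :func:`write_dataset`."""
    indir = Path(indir)
    with open(indir / "design.json") as fh:
        spec = json.load(fh)
    return assemble_dataset(
        pd.read_csv(indir / "replicates.csv"),
        pd.read_csv(indir / "site_covariates.csv"),
        pd.read_csv(indir / "sample_covariates.csv"),
        pd.read_csv(indir / "standards.csv"),
        spec)
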