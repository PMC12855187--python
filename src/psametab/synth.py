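"""Synthetic serum-metabolomics cohorts.

Generates two-group cohorts (active psoriatic-arthritis patients vs healthy
controls) with the statistical structure of the study population this
package targets: 13 serum metabolites with group-specific means and SDs in
relative-concentration units, a disease-activity score (DAPSA) for the
patient group that is rank-correlated with selected metabolites through a
Gaussian copula, and optionally rendered 1D NMR spectra so the bucketing
front-end can be exercised end to end.

Default parameters encode the reference cohort: n=29 patients / n=33
controls, the 13 metabolite group means/SDs, DAPSA mean 25.2 and SD 10.4
with every score above the activity floor of 14, and target Spearman
correlations of 0.384 (alanine) and 0.487 (leucine) with DAPSA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import brentq

from .spectra import SpectrumSet

__all__ = [
    "GroupParams",
    "DapsaLink",
    "SpectralLibrary",
    "SyntheticCohort",
    "generate_concentrations",
    "generate_dapsa",
    "render_spectra",
    "generate_cohort",
    "solve_truncated_normal",
    "spearman_to_pearson",
    "METABOLITES",
]

# Group means and SDs in relative-concentration units (percent of total
# molar concentration), patient group first.
_TABLE = [
    # name,               mean_psa, sd_psa, mean_hc, sd_hc
    ("2-aminobutyrate",     1.911,  0.314,  1.900,  0.273),
    ("alanine",             7.010,  1.416,  8.402,  1.499),
    ("anserine",            2.509,  0.739,  2.753,  0.635),
    ("glucose",            52.43,   5.242, 48.340,  3.514),
    ("glutamine",           9.739,  2.817, 11.080,  1.618),
    ("glycylproline",       4.353,  1.801,  3.411,  1.127),
    ("isoleucine",          1.500,  0.245,  1.688,  0.294),
    ("leucine",             2.601,  0.470,  3.124,  0.508),
    ("methionine",          0.6879, 0.207,  0.8190, 0.130),
    ("serine",              5.2170, 0.914,  6.008,  0.729),
    ("threonate",           6.601,  1.109,  6.412,  0.997),
    ("tryptophan",          1.252,  0.239,  1.349,  0.217),
    ("valine",              4.189,  0.837,  4.769,  0.781),
]

METABOLITES = [row[0] for row in _TABLE]


def _exchangeable(p: int, rho: float) -> np.ndarray:
    R = np.full((p, p), rho, dtype=float)
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class GroupParams:
    """Per-metabolite location/scale for each group plus a shared
    metabolite-metabolite correlation matrix (default exchangeable,
    rho=0.1; the reference study reports no covariance information)."""

    metabolite_names: list[str]
    means_psa: np.ndarray
    sds_psa: np.ndarray
    means_hc: np.ndarray
    sds_hc: np.ndarray
    correlation: np.ndarray

    def __post_init__(self):
        p = len(self.metabolite_names)
        for name in ("means_psa", "sds_psa", "means_hc", "sds_hc"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (p,):
                raise ValueError(f"{name} must have length {p}")
            setattr(self, name, arr)
        if np.any(self.sds_psa <= 0) or np.any(self.sds_hc <= 0):
            raise ValueError("all SDs must be positive")
        R = np.asarray(self.correlation, dtype=float)
        if R.shape != (p, p) or not np.allclose(R, R.T) \
                or not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation must be symmetric with unit diagonal")
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix is not positive definite") from exc
        self.correlation = R

    @classmethod
    def default(cls, rho: float = 0.1) -> "GroupParams":
        return cls(
            metabolite_names=list(METABOLITES),
            means_psa=np.array([r[1] for r in _TABLE]),
            sds_psa=np.array([r[2] for r in _TABLE]),
            means_hc=np.array([r[3] for r in _TABLE]),
            sds_hc=np.array([r[4] for r in _TABLE]),
            correlation=_exchangeable(len(_TABLE), rho),
        )

    def to_dict(self) -> dict:
        return {
            "metabolite_names": self.metabolite_names,
            "means_psa": self.means_psa.tolist(),
            "sds_psa": self.sds_psa.tolist(),
            "means_hc": self.means_hc.tolist(),
            "sds_hc": self.sds_hc.tolist(),
            "correlation": self.correlation.tolist(),
        }


@dataclass
class DapsaLink:
    """Copula link between patient DAPSA scores and metabolite levels.

    ``target_spearman`` maps metabolite name to the rank correlation the
    generated scores should reach.  DAPSA follows a left-truncated normal
    above ``dapsa_floor`` whose parent parameters are solved so that the
    truncated distribution itself has mean ``dapsa_mean`` and SD
    ``dapsa_sd``.
    """

    target_spearman: dict[str, float] = field(
        default_factory=lambda: {"alanine": 0.384, "leucine": 0.487})
    dapsa_mean: float = 25.2
    dapsa_sd: float = 10.4
    dapsa_floor: float = 14.0

    def __post_init__(self):
        for name, r in self.target_spearman.items():
            if not abs(r) < 1:
                raise ValueError(f"|target_spearman| must be < 1 ({name}: {r})")
        if not self.dapsa_mean > self.dapsa_floor:
            raise ValueError("dapsa_mean must exceed dapsa_floor")


def spearman_to_pearson(r_s: float) -> float:
    """Latent Pearson correlation giving Spearman ``r_s`` under a
    bivariate Gaussian copula: rho = 2 sin(pi r_s / 6)."""
    return 2.0 * np.sin(np.pi * r_s / 6.0)


@lru_cache(maxsize=32)
def solve_truncated_normal(mean: float, sd: float, floor: float):
    """Parent (mu, sigma) of a normal left-truncated at ``floor`` whose
    truncated distribution has the requested mean and SD.

    Solved by root-finding on the standardized truncation point alpha:
    with lam = phi(alpha)/(1-Phi(alpha)), the truncated mean is
    mu + sigma*lam and the variance sigma^2 (1 + alpha*lam - lam^2); the
    ratio (mean-floor)/sd = (lam-alpha)/sqrt(1+alpha*lam-lam^2) is strictly
    decreasing in alpha.
    """
    target = (mean - floor) / sd
    if target <= 0:
        raise ValueError("mean must exceed floor")

    def lam(a):
        return stats.norm.pdf(a) / stats.norm.sf(a)

    def g(a):
        l = lam(a)
        return (l - a) / np.sqrt(1.0 + a * l - l * l) - target

    alpha = brentq(g, -30.0, 30.0, xtol=1e-12)
    l = lam(alpha)
    sigma = sd / np.sqrt(1.0 + alpha * l - l * l)
    mu = floor - alpha * sigma
    return mu, sigma


def generate_concentrations(params: GroupParams | None = None,
                            n_psa: int = 29, n_hc: int = 33,
                            seed: int = 0):
    """Draw a two-group concentration table.

    Each group's metabolite vector is multivariate Gaussian with the
    group's means/SDs and the configured correlation, truncated at zero by
    redrawing any sample row containing a negative value (preserves the
    means; the truncated mass is negligible at the default parameters).

    Returns
    -------
    (conc, cohort) : concentration DataFrame (samples x metabolites) and a
    cohort DataFrame with ``sample_id`` index and ``group`` column.
    """
    params = params or GroupParams.default()
    if n_psa < 2 or n_hc < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(params.correlation)
    p = len(params.metabolite_names)

    def draw(n, means, sds):
        out = np.empty((n, p))
        todo = np.arange(n)
        for _ in range(200):
            z = rng.standard_normal((todo.size, p)) @ L.T
            out[todo] = means + sds * z
            neg = np.any(out[todo] < 0, axis=1)
            todo = todo[neg]
            if todo.size == 0:
                break
        else:
            raise RuntimeError("zero-truncation redraw did not terminate")
        return out

    x_psa = draw(n_psa, params.means_psa, params.sds_psa)
    x_hc = draw(n_hc, params.means_hc, params.sds_hc)
    ids = [f"PsA{i + 1:03d}" for i in range(n_psa)] + \
          [f"HC{i + 1:03d}" for i in range(n_hc)]
    conc = pd.DataFrame(np.vstack([x_psa, x_hc]), index=pd.Index(ids, name="sample_id"),
                        columns=params.metabolite_names)
    cohort = pd.DataFrame({"group": ["PsA"] * n_psa + ["HC"] * n_hc},
                          index=conc.index)
    return conc, cohort


def generate_dapsa(cohort: pd.DataFrame, conc: pd.DataFrame,
                   link: DapsaLink | None = None, seed: int = 0) -> pd.DataFrame:
    """Attach DAPSA scores (patient rows only) via a Gaussian copula.

    A latent standard normal u is built with Pearson correlation
    2 sin(pi r_s/6) to each linked metabolite's latent score, then
    quantile-mapped onto the moment-matched left-truncated normal.  Since
    the concentration margins are (negligibly truncated) Gaussians, the
    standardized observed columns serve as the latent scores; their mutual
    correlation is estimated from the sample.
    """
    link = link or DapsaLink()
    psa_mask = cohort["group"] == "PsA"
    if not psa_mask.any():
        raise ValueError("cohort contains no PsA rows")
    missing = [m for m in link.target_spearman if m not in conc.columns]
    if missing:
        raise ValueError(f"linked metabolites absent from table: {missing}")

    rng = np.random.default_rng(seed)
    idx = cohort.index[psa_mask]
    names = list(link.target_spearman)
    rho = np.array([spearman_to_pearson(link.target_spearman[m]) for m in names])

    if names:
        Z = conc.loc[idx, names].to_numpy(float)
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
        if len(names) > 1 and len(idx) > 2:
            S = np.corrcoef(Z, rowvar=False)
            # guard against near-singular small-sample estimates
            vals, vecs = np.linalg.eigh(S)
            if vals.min() < 0.05:
                S = vecs @ np.diag(np.maximum(vals, 0.05)) @ vecs.T
                d = np.sqrt(np.diag(S))
                S = S / np.outer(d, d)
        else:
            S = np.eye(len(names))
        try:
            w = np.linalg.solve(S, rho)
        except np.linalg.LinAlgError as exc:
            raise ValueError("degenerate latent correlation among linked "
                             f"metabolites {names}") from exc
        resid = 1.0 - float(rho @ w)
        if resid <= 0:
            raise ValueError(
                "infeasible joint correlation: targets for "
                f"{names} imply a non-positive-definite latent matrix")
        u = Z @ w + np.sqrt(resid) * rng.standard_normal(len(idx))
        u = u / np.sqrt(float(w @ S @ w) + resid)
    else:
        u = rng.standard_normal(len(idx))

    mu, sigma = solve_truncated_normal(link.dapsa_mean, link.dapsa_sd,
                                       link.dapsa_floor)
    a = (link.dapsa_floor - mu) / sigma
    dapsa = stats.truncnorm.ppf(stats.norm.cdf(u), a, np.inf,
                                loc=mu, scale=sigma)
    out = cohort.copy()
    out["dapsa"] = np.nan
    out.loc[idx, "dapsa"] = dapsa
    return out


@dataclass
class SpectralLibrary:
    """Chemical-shift library used by the spectrum renderer.

    ``metabolites`` maps name -> list of multiplets, each a dict with
    ``center`` (ppm), ``area`` (relative), ``width`` (Lorentzian HWHM,
    ppm).  Shipped as an editable YAML data file; the shift values follow
    standard reference compilations but downstream code relies only on
    internal consistency.
    """

    metabolites: dict[str, list[dict]]
    tsp: dict
    water: dict
    jitter_sd: float = 0.005
    noise_sd: float = 0.002

    def __post_init__(self):
        for name, mults in self.metabolites.items():
            for m in mults:
                if not (0.0 <= m["center"] <= 8.5):
                    raise ValueError(f"{name}: multiplet center outside 0-8.5 ppm")
                if m["area"] <= 0:
                    raise ValueError(f"{name}: multiplet area must be positive")

    @classmethod
    def default(cls) -> "SpectralLibrary":
        text = resources.files("psametab.data").joinpath(
            "spectral_library.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def load(cls, path) -> "SpectralLibrary":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralLibrary":
        return cls(metabolites=d["metabolites"], tsp=d["tsp"],
                   water=d["water"], jitter_sd=d.get("jitter_sd", 0.005),
                   noise_sd=d.get("noise_sd", 0.002))


def _lorentzian(ppm: np.ndarray, center: float, hwhm: float,
                area: float) -> np.ndarray:
    return (area / np.pi) * hwhm / ((ppm - center) ** 2 + hwhm ** 2)


def render_spectra(conc: pd.DataFrame, lib: SpectralLibrary | None = None,
                   n_points: int = 16384, seed: int = 0,
                   ppm_range: tuple[float, float] = (0.0, 8.60)) -> SpectrumSet:
    """Render each sample's concentration vector as a 1D NMR spectrum.

    Every metabolite contributes Lorentzian multiplets with total area
    proportional to its concentration; each multiplet's position receives
    per-sample Gaussian jitter (emulating pH-driven chemical-shift
    variation), a Gaussian residual-water band sits inside 4.70-5.20 ppm, a
    TSP reference peak sits at 0.00 ppm, and additive Gaussian noise is
    applied.
    """
    lib = lib or SpectralLibrary.default()
    if n_points < 2048:
        raise ValueError("n_points must be at least 2048")
    missing = [m for m in conc.columns if m not in lib.metabolites]
    if missing:
        raise ValueError(f"metabolites without library entries: {missing}")

    rng = np.random.default_rng(seed)
    ppm = np.linspace(ppm_range[0], ppm_range[1], n_points)
    spectra = np.zeros((len(conc), n_points))
    values = conc.to_numpy(float)
    for s in range(len(conc)):
        y = spectra[s]
        for j, name in enumerate(conc.columns):
            c = values[s, j]
            for mult in lib.metabolites[name]:
                center = mult["center"] + rng.normal(0.0, lib.jitter_sd)
                y += _lorentzian(ppm, center, mult["width"], c * mult["area"])
        # residual water: Gaussian band, per-sample amplitude variation
        wamp = lib.water["area"] * rng.uniform(0.5, 1.5)
        wsd = lib.water["width"]
        y += wamp / (wsd * np.sqrt(2 * np.pi)) * \
            np.exp(-0.5 * ((ppm - lib.water["center"]) / wsd) ** 2)
        y += _lorentzian(ppm, lib.tsp["center"], lib.tsp["width"],
                         lib.tsp["area"])
        if lib.noise_sd > 0:
            y += rng.normal(0.0, lib.noise_sd, n_points)
    return SpectrumSet(ppm=ppm, intensities=spectra,
                       sample_ids=[str(i) for i in conc.index])


@dataclass
class SyntheticCohort:
    """A generated cohort plus the full parameter record that produced it."""

    cohort: pd.DataFrame
    concentrations: pd.DataFrame
    spectra: SpectrumSet | None
    seed: int
    params: dict

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = self.cohort.copy()
        meta.to_csv(outdir / "cohort.tsv", sep="\t")
        self.concentrations.to_csv(outdir / "concentrations.tsv", sep="\t")
        if self.spectra is not None:
            self.spectra.to_tsv(outdir / "spectra.tsv")
        (outdir / "generator.json").write_text(
            json.dumps({"seed": self.seed, **self.params}, indent=2))


def generate_cohort(params: GroupParams | None = None,
                    link: DapsaLink | None = None,
                    n_psa: int = 29, n_hc: int = 33, seed: int = 0,
                    spectra: bool = False,
                    lib: SpectralLibrary | None = None) -> SyntheticCohort:
    """One-call cohort generation: concentrations, DAPSA, optional spectra.

    Stage seeds are derived deterministically from ``seed`` so each stage
    can be reproduced in isolation.
    """
    params = params or GroupParams.default()
    link = link or DapsaLink()
    conc, cohort = generate_concentrations(params, n_psa, n_hc, seed=seed)
    cohort = generate_dapsa(cohort, conc, link, seed=seed + 1)
    spec = render_spectra(conc, lib, seed=seed + 2) if spectra else None
    record = {"n_psa": n_psa, "n_hc": n_hc, "group_params": params.to_dict(),
              "dapsa_link": {"target_spearman": link.target_spearman,
                             "mean": link.dapsa_mean, "sd": link.dapsa_sd,
                             "floor": link.dapsa_floor},
              "spectra": spectra}
    return SyntheticCohort(cohort=cohort, concentrations=conc, spectra=spec,
                           seed=seed, params=record)
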