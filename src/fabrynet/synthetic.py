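"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a plasma targeted-metabolomics case/control study of
a lysosomal storage disease: 60 controls and 66 patients measured on a
188-metabolite panel whose class composition mirrors the Biocrates p180 kit
(40 acylcarnitines, 21 amino acids, 21 biogenic amines, 76 diacyl/acyl-alkyl
glycerophospholipids, 14 lysophosphatidylcholines, 15 sphingomyelins and the
hexose sum).

Log-concentrations are multivariate normal.  The control group follows a
sparse Gaussian graphical model (planted partial-correlation edges); the
patient group shares that conditional-independence structure plus a set of
disease-only edges concentrated on a small "disease module", and receives
mean shifts on a planted subset of metabolites.  Small additive sex and age
effects and sporadic missingness complete the picture.  Everything is
recorded in a :class:`SimulationTruth` so downstream recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_data import MetaboliteMatrix, SampleMetadata, MetaboliteAnnotation

# p180-style panel composition (class -> count at the default 188 metabolites)
P180_COMPOSITION = {
    "acylcarnitine": 40,
    "amino_acid": 21,
    "biogenic_amine": 21,
    "glycerophospholipid": 76,
    "lysophosphatidylcholine": 14,
    "sphingomyelin": 15,
    "hexoses": 1,
}

_CLASS_PREFIX = {
    "acylcarnitine": "AC",
    "amino_acid": "AA",
    "biogenic_amine": "BA",
    "glycerophospholipid": "PC",
    "lysophosphatidylcholine": "lysoPC",
    "sphingomyelin": "SM",
    "hexoses": "H",
}

_PD_EPS = 0.05  # smallest eigenvalue enforced on precision matrices


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults are the study conditions."""

    n_control: int = 60
    n_fabry: int = 66
    n_metabolites: int = 188
    n_differential: int = 86
    effect_size: float = 1.5        # group mean shift, within-group log-SD units
    edge_density: float = 0.03      # control partial-correlation graph density
    pcor_range: tuple[float, float] = (0.2, 0.5)
    disease_module_size: int = 13   # nodes receiving extra disease-only edges
    # disease-only edges chain the module metabolites (substrate/product-style
    # co-accumulation) with alternating strong and moderate links; low degree
    # keeps strong partial correlations positive-definite-feasible.  Strong
    # links must survive dilution by the control half of the combined sample;
    # moderate links sit near the detection boundary, as real disease edges
    # diluted by controls do.
    disease_pcor_range: tuple[float, float] = (0.6, 0.75)
    disease_pcor_weak_range: tuple[float, float] = (0.35, 0.45)
    sex_effect_sd: float = 0.1      # additive male shift, log-SD units
    age_effect_sd: float = 0.005    # additive slope per year, log-SD units
    severity_sigma: float = 1.0     # patient-to-patient lognormal spread of
                                    # disease-module deviations (severity spectrum)
    missing_rate: float = 0.02
    missing_mode: str = "mcar"      # "mcar" or "censored" (low values preferentially)
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_differential > self.n_metabolites:
            raise ValueError("n_differential cannot exceed n_metabolites")
        if self.disease_module_size > self.n_metabolites:
            raise ValueError("disease module cannot exceed the metabolite set")
        for rng_name in ("pcor_range", "disease_pcor_range", "disease_pcor_weak_range"):
            lo, hi = getattr(self, rng_name)
            if not (0 < lo <= hi < 1):
                raise ValueError(f"{rng_name} must satisfy 0 < lo <= hi < 1")
        if self.missing_mode not in ("mcar", "censored"):
            raise ValueError("missing_mode must be 'mcar' or 'censored'")


@dataclass
class SimulationTruth:
    """What was planted: differential metabolites and graph structure."""

    differential: list  # (metabolite_id, signed shift in log-SD units)
    control_edges: list  # (a, b, realized pcor)
    disease_only_edges: list  # (a, b, realized pcor in the disease graph)
    disease_module: list  # metabolite ids

    def differential_ids(self) -> set:
        return {m for m, _ in self.differential}

    def control_edge_set(self) -> set:
        return {frozenset((a, b)) for a, b, _ in self.control_edges}

    def disease_edge_set(self) -> set:
        return {frozenset((a, b)) for a, b, _ in self.disease_only_edges}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            differential=[tuple(x) for x in d["differential"]],
            control_edges=[tuple(x) for x in d["control_edges"]],
            disease_only_edges=[tuple(x) for x in d["disease_only_edges"]],
            disease_module=list(d["disease_module"]),
        )


# ---------------------------------------------------------------------------
# panel / graph construction
# ---------------------------------------------------------------------------


def panel_annotation(n_metabolites: int = 188) -> MetaboliteAnnotation:
    """Metabolite ids and classes in p180 proportions."""
    total = sum(P180_COMPOSITION.values())
    counts = {c: max(1, round(n_metabolites * k / total)) for c, k in P180_COMPOSITION.items()}
    # adjust the largest class so counts sum exactly
    drift = n_metabolites - sum(counts.values())
    counts["glycerophospholipid"] += drift
    ids, classes = [], []
    for cls, k in counts.items():
        prefix = _CLASS_PREFIX[cls]
        for i in range(1, k + 1):
            ids.append(f"{prefix}{i:02d}" if k > 1 else prefix + "1")
            classes.append(cls)
    return MetaboliteAnnotation(pd.DataFrame({"class": classes}, index=pd.Index(ids, name="metabolite_id")))


def _modular_edges(rng: np.random.Generator, p: int, n_edges: int) -> list:
    """Control-graph edge set with modular, nearly banded topology.

    Metabolite panels are strongly modular — adjacent species within a
    biochemical class (e.g. phosphatidylcholines of neighbouring chain
    length) correlate, with only sparse cross-class links.  Chains of
    nearest and next-nearest neighbours within blocks of ~10, plus isolated
    random pairs, reproduce that and keep the precision matrix close to
    positive definite, so planted partial correlations survive the PD
    projection nearly unchanged.
    """
    edges: list = []
    block = 10
    for start in range(0, p - 1, block):
        stop = min(start + block, p)
        for i in range(start, stop - 1):
            edges.append((i, i + 1))
        for i in range(start, stop - 2, 2):
            edges.append((i, i + 2))
    if len(edges) > n_edges:
        keep = rng.choice(len(edges), size=n_edges, replace=False)
        return sorted(edges[i] for i in keep)
    have = set(edges)
    while len(edges) < n_edges:  # sparse long-range pairs
        a, b = rng.integers(0, p, size=2)
        pair = (min(a, b), max(a, b))
        if a == b or pair in have:
            continue
        have.add(pair)
        edges.append(pair)
    return sorted(edges)


def _load_to_pd(omega: np.ndarray, eps: float = _PD_EPS) -> tuple[np.ndarray, float]:
    """Diagonal loading to the nearest comfortably positive-definite matrix."""
    lam_min = float(np.linalg.eigvalsh(omega)[0])
    delta = max(0.0, eps - lam_min)
    if delta > 0:
        omega = omega + delta * np.eye(omega.shape[0])
    return omega, delta


def _pcor_from_precision(omega: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def build_precision_matrices(
    cfg: SimulationConfig, rng: np.random.Generator, module_pool=None
):
    """Control and disease precision matrices with planted pcor edges.

    Off-diagonal entries are set to the negated target partial correlation;
    diagonal loading then guarantees positive definiteness (required for a
    valid Gaussian), which rescales the realized partial correlations — the
    realized values are returned alongside the edge lists.  ``module_pool``
    restricts which metabolites the disease module is drawn from (the cohort
    generator passes the differential set: the consensus-signature
    metabolites of such a study are themselves disease-regulated).
    """
    p = cfg.n_metabolites
    n_pairs = p * (p - 1) // 2
    n_ctrl_edges = max(1, round(cfg.edge_density * n_pairs))
    ctrl_pairs = _modular_edges(rng, p, n_ctrl_edges)

    lo, hi = cfg.pcor_range
    omega0 = np.eye(p)
    for a, b in ctrl_pairs:
        rho = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        omega0[a, b] = omega0[b, a] = -rho

    pool = np.arange(p) if module_pool is None or len(module_pool) < cfg.disease_module_size else np.asarray(module_pool)
    module = sorted(rng.choice(pool, size=cfg.disease_module_size, replace=False))
    # chain the module nodes with alternating strong/moderate links; degree
    # stays <= 2 so strong partial correlations remain PD-feasible
    perm = list(rng.permutation(module))
    chain = [
        (min(perm[i], perm[i + 1]), max(perm[i], perm[i + 1]))
        for i in range(len(perm) - 1)
    ]
    ctrl_set = set(ctrl_pairs)
    chain = [pr for pr in dict.fromkeys(chain) if pr not in ctrl_set]
    strong_pairs = chain[0::2]
    weak_pairs = chain[1::2]
    disease_pairs = sorted(chain)

    omega_c, _ = _load_to_pd(omega0)
    # disease-only edges are written onto the loaded control precision with
    # entries targeting the partial correlation directly, so they stay strong
    # after the (small) extra loading the disease matrix needs
    dlo, dhi = cfg.disease_pcor_range
    wlo, whi = cfg.disease_pcor_weak_range
    rho_d = {}
    for pair in strong_pairs:
        rho_d[pair] = rng.uniform(dlo, dhi) * rng.choice([-1.0, 1.0])
    for pair in weak_pairs:
        rho_d[pair] = rng.uniform(wlo, whi) * rng.choice([-1.0, 1.0])
    omega_d = omega_c
    for _ in range(3):  # re-target entries after each loading pass
        omega_d0 = omega_c.copy()
        diag = np.sqrt(np.diag(omega_d))
        for (a, b), rho in rho_d.items():
            omega_d0[a, b] = omega_d0[b, a] = -rho * diag[a] * diag[b]
        omega_d, delta = _load_to_pd(omega_d0)
        if delta == 0:
            break
    if np.linalg.eigvalsh(omega_c)[0] <= 0 or np.linalg.eigvalsh(omega_d)[0] <= 0:
        raise ValueError(
            "requested structure is not positive definite even after diagonal "
            "boosting; lower edge_density or pcor magnitudes"
        )
    return omega_c, omega_d, ctrl_pairs, disease_pairs, module


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(cfg: SimulationConfig | None = None):
    """Draw one cohort.

    Returns ``(matrix, metadata, annotation, truth)``: a raw-scale µM
    concentration matrix with missingness, the clinical covariates, the
    panel annotation, and the planted ground truth.  Identical config (incl.
    seed) gives identical output.
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    anno = panel_annotation(cfg.n_metabolites)
    met_ids = anno.metabolite_ids
    p = cfg.n_metabolites

    # the disease module lives inside the differential set: consensus-type
    # metabolites of such a cohort are themselves disease-regulated
    diff_idx = np.sort(rng.choice(p, size=cfg.n_differential, replace=False))
    omega_c, omega_d, ctrl_pairs, disease_pairs, module_idx = build_precision_matrices(
        cfg, rng, module_pool=diff_idx
    )
    sigma_c = np.linalg.inv(omega_c)
    sigma_d = np.linalg.inv(omega_d)
    pcor_c = _pcor_from_precision(omega_c)
    pcor_d = _pcor_from_precision(omega_d)

    # per-metabolite location/scale on the natural-log scale:
    # concentrations span ~0.05-200 µM, biological log-SD ~0.2-0.6
    baseline = rng.uniform(np.log(0.05), np.log(200.0), size=p)
    met_scale = rng.uniform(0.2, 0.6, size=p)
    sd_c = met_scale * np.sqrt(np.diag(sigma_c))  # within-control log-SD
    diff_sign = rng.choice([-1.0, 1.0], size=cfg.n_differential)
    shift = np.zeros(p)
    shift[diff_idx] = diff_sign * cfg.effect_size * sd_c[diff_idx]

    cov_sign = rng.choice([-1.0, 1.0], size=p)
    n_c, n_f = cfg.n_control, cfg.n_fabry
    n = n_c + n_f

    sexes_c = np.array(["F", "M"] * ((n_c + 1) // 2))[:n_c]
    sexes_f = np.array(["F", "M"] * ((n_f + 1) // 2))[:n_f]
    ages_c = rng.uniform(18, 56, size=n_c)
    ages_f = rng.uniform(17, 75, size=n_f)
    ages = np.concatenate([ages_c, ages_f])
    sexes = np.concatenate([sexes_c, sexes_f])
    male = (sexes == "M").astype(float)
    age_c = ages - ages.mean()

    z_c = rng.multivariate_normal(np.zeros(p), sigma_c, size=n_c, method="cholesky")
    z_f = rng.multivariate_normal(np.zeros(p), sigma_d, size=n_f, method="cholesky")
    # severity spectrum: each patient's disease-module deviations are scaled
    # by a lognormal factor, emulating mild-to-severe clinical heterogeneity
    if cfg.severity_sigma > 0 and module_idx:
        severity = np.exp(rng.normal(0.0, cfg.severity_sigma, size=n_f))
        z_f[:, module_idx] *= severity[:, None]
    z = np.vstack([z_c, z_f]) * met_scale  # diagonal scaling keeps pcor intact

    group_ind = np.concatenate([np.zeros(n_c), np.ones(n_f)])
    logx = (
        baseline
        + z
        + np.outer(group_ind, shift)
        + np.outer(male, cov_sign * cfg.sex_effect_sd * sd_c)
        + np.outer(age_c, cov_sign * cfg.age_effect_sd * sd_c)
    )
    values = np.exp(logx)

    if cfg.missing_rate > 0:
        if cfg.missing_mode == "mcar":
            mask = rng.random(values.shape) < cfg.missing_rate
        else:  # censored: the lowest concentrations drop out preferentially
            ranks = values.argsort(axis=0).argsort(axis=0) / (n - 1)
            prob = cfg.missing_rate * 2 * (1 - ranks)
            mask = rng.random(values.shape) < prob
        values = np.where(mask, np.nan, values)

    sample_ids = [f"CTRL{i+1:03d}" for i in range(n_c)] + [f"FAB{i+1:03d}" for i in range(n_f)]
    matrix = MetaboliteMatrix(
        pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"), columns=met_ids),
        scale="raw",
    )

    phen = np.where(np.arange(n_f) % 2 == 0, "classical", "non_classical")
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "group": ["control"] * n_c + ["fabry"] * n_f,
                "sex": sexes,
                "age": np.round(ages, 1),
                "phenotype": ["not_applicable"] * n_c + list(phen),
                "treated": ["not_applicable"] * n_c + list(rng.random(n_f) < 0.68),
                "lysoGb3": np.nan,
                "residual_enzyme_activity": np.nan,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    truth = SimulationTruth(
        differential=[(met_ids[j], float(s)) for j, s in zip(diff_idx, diff_sign * cfg.effect_size)],
        control_edges=[(met_ids[a], met_ids[b], float(pcor_c[a, b])) for a, b in ctrl_pairs],
        disease_only_edges=[(met_ids[a], met_ids[b], float(pcor_d[a, b])) for a, b in disease_pairs],
        disease_module=[met_ids[j] for j in module_idx],
    )
    return matrix, meta, anno, truth


def attach_biomarkers(
    meta: SampleMetadata,
    matrix: MetaboliteMatrix,
    truth: SimulationTruth,
    seed: int,
    rho_lysogb3: float = 0.5,
    rho_rea: float = -0.5,
    metabolite: str | None = None,
) -> SampleMetadata:
    """Fill patient LysoGb3 and residual enzyme activity.

    Both biomarkers are generated with a configurable rank correlation to a
    chosen planted differential metabolite (Gaussian-copula construction on
    normal scores, so the requested rho is approximately the Spearman rho).
    LysoGb3 is log-normal and elevated in patients; residual enzyme activity
    is low (fractions of control activity).  Controls keep missing values.
    """
    for name, rho in (("rho_lysogb3", rho_lysogb3), ("rho_rea", rho_rea)):
        if not -1 < rho < 1:
            raise ValueError(f"{name} must lie strictly inside (-1, 1)")
    fabry_ids = meta.ids_of("fabry")
    if not fabry_ids:
        raise ValueError("no Fabry samples in metadata")
    if metabolite is None:
        if not truth.differential:
            raise ValueError("no planted differential metabolite to correlate with")
        metabolite = truth.differential[0][0]

    rng = np.random.default_rng(seed)
    x = matrix.data.loc[fabry_ids, metabolite].to_numpy(dtype=float)
    # normal scores of the metabolite (missing values get a random score)
    x_filled = np.where(np.isnan(x), rng.normal(size=x.size), x)
    order = np.argsort(np.argsort(x_filled))
    from scipy import stats

    z = stats.norm.ppf((order + 0.5) / x.size)

    def coupled(rho: float) -> np.ndarray:
        # requested rho is a rank correlation: convert to the Pearson mixing
        # coefficient of the Gaussian copula (rho_p = 2 sin(pi rho_s / 6))
        rho_p = 2 * np.sin(np.pi * rho / 6)
        return rho_p * z + np.sqrt(1 - rho_p**2) * rng.normal(size=x.size)

    lyso = np.exp(np.log(30.0) + 0.6 * coupled(rho_lysogb3))  # ng/mL, elevated
    rea = 0.4 / (1 + np.exp(-coupled(rho_rea)))               # low fractions

    out = meta.copy()
    out.table.loc[fabry_ids, "lysoGb3"] = lyso
    out.table.loc[fabry_ids, "residual_enzyme_activity"] = rea
    return out
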