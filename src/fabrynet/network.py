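"""Shrinkage partial-correlation networks, pruning, and consensus signatures.

The disease-specific workflow:

1. estimate a shrunken partial-correlation matrix (PCM) on three sample
   regimes — all samples, controls only, and controls + patients-minus-one
   (one PCM per left-out patient);
2. turn each PCM into a sparse graph by keeping the strongest edges;
3. *prune*: remove from a general network every edge also present in a more
   specific network.  Pruning "control + disease" by "control" keeps the
   disease-specific edges; pruning each leave-one-patient-out network by
   the control network and then by the disease-specific network leaves a
   patient-specific signature (the metabolites whose disease edges vanish
   when that patient is removed);
4. the metabolites present in all patient-specific signatures form the
   consensus signature.

Partial correlations use the analytic variance-minimizing shrinkage of the
sample correlation matrix toward the identity, which keeps the estimate
invertible even with more metabolites than samples (188 vs <= 126 here):

    R* = (1 - lambda) R + lambda I,   lambda* = sum Var(r_ij) / sum r_ij^2
    pcor_ij = -Omega_ij / sqrt(Omega_ii Omega_jj),  Omega = (R*)^{-1}
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core_data import MetaboliteMatrix, SampleMetadata


# ---------------------------------------------------------------------------
# partial correlation estimation
# ---------------------------------------------------------------------------


def shrinkage_lambda(x: np.ndarray) -> float:
    """Analytic variance-minimizing shrinkage intensity toward identity.

    ``x`` is samples x variables.  Uses the unbiased estimate of the
    variance of each correlation coefficient from the standardized data
    products; clamped to [0, 1].
    """
    n, p = x.shape
    if n <= 2:
        raise ValueError("shrinkage intensity undefined for n <= 2 samples")
    xs = (x - x.mean(axis=0))
    sd = xs.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    xs = xs / sd
    # r_ij = sum_k w_kij / (n-1) with w_kij = xs_ki * xs_kj
    s1 = xs.T @ xs                      # sum_k w_kij
    s2 = (xs**2).T @ (xs**2)            # sum_k w_kij^2
    var_w = (s2 - s1**2 / n) / (n - 1)  # sample variance of w over k
    var_r = var_w * n / (n - 1) ** 2    # Var(r_ij) estimate
    r = s1 / (n - 1)
    off = ~np.eye(p, dtype=bool)
    denom = float((r[off] ** 2).sum())
    if denom == 0:
        return 1.0
    lam = float(var_r[off].sum()) / denom
    return min(1.0, max(0.0, lam))


def estimate_pcor(
    x_or_matrix, shrinkage: str | float = "analytic"
) -> tuple[pd.DataFrame, float]:
    """Shrunken partial-correlation matrix of a sample subset.

    ``shrinkage`` is ``"analytic"`` (default) or a fixed lambda in [0, 1].
    Returns the pcor DataFrame (unit diagonal) and the lambda used.
    """
    if isinstance(x_or_matrix, MetaboliteMatrix):
        data = x_or_matrix.data
    else:
        data = x_or_matrix
    x = data.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("partial correlations require a fully observed matrix")
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples to estimate partial correlations")
    if shrinkage == "analytic":
        lam = shrinkage_lambda(x)
    else:
        lam = float(shrinkage)
        if not 0 <= lam <= 1:
            raise ValueError("fixed shrinkage lambda must lie in [0, 1]")
    sd = x.std(axis=0, ddof=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    xs = (x - x.mean(axis=0)) / sd_safe
    r = (xs.T @ xs) / (n - 1)
    np.fill_diagonal(r, 1.0)
    r_star = (1 - lam) * r + lam * np.eye(p)
    omega = np.linalg.inv(r_star)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pd.DataFrame(pcor, index=data.columns, columns=data.columns), lam


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


@dataclass
class PcorNetwork:
    """Undirected weighted graph of metabolites (weights = partial correlations)."""

    edges: dict  # frozenset({a, b}) -> float weight
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for pair, w in self.edges.items():
            if len(pair) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(pair)}")
            if not -1 < w < 1:
                raise ValueError(f"edge weight {w} outside (-1, 1) for {set(pair)}")

    @property
    def nodes(self) -> set:
        out: set = set()
        for pair in self.edges:
            out |= pair
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set:
        return set(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(provenance=self.provenance)
        for pair, w in self.edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, pcor=float(w))
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [(min(p), max(p), w) for p, w in self.edges.items()]
        rows.sort()
        return pd.DataFrame(rows, columns=["node_a", "node_b", "pcor"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_edge_list(self, path) -> None:
        self.to_edge_frame().to_csv(path, index=False)


def build_network(
    pcor: pd.DataFrame,
    edge_rule: str = "quantile",
    q: float = 0.05,
    tau: float = 0.5,
    provenance: str = "unspecified",
) -> PcorNetwork:
    """Threshold a partial-correlation matrix into a sparse graph.

    ``quantile`` (default): keep the top ``q`` fraction of off-diagonal
    |pcor| values — exactly ceil(q * m(m-1)/2) edges, ties broken by the
    lexicographically smaller node pair.  ``absolute``: keep |pcor| >= tau.
    Nodes are the endpoints of kept edges.
    """
    m = pcor.shape[0]
    ids = list(pcor.index)
    vals = pcor.to_numpy(dtype=float)
    iu = np.triu_indices(m, k=1)
    pairs = [(ids[i], ids[j]) for i, j in zip(*iu)]
    weights = vals[iu]
    if edge_rule == "quantile":
        if not 0 < q < 1:
            raise ValueError("quantile q must lie in (0, 1)")
        k = int(np.ceil(q * len(pairs)))
        order = sorted(range(len(pairs)), key=lambda i: (-abs(weights[i]), pairs[i]))
        keep = order[:k]
    elif edge_rule == "absolute":
        if not 0 < tau < 1:
            raise ValueError("absolute threshold tau must lie in (0, 1)")
        keep = [i for i in range(len(pairs)) if abs(weights[i]) >= tau]
    else:
        raise ValueError("edge_rule must be 'quantile' or 'absolute'")
    edges = {frozenset(pairs[i]): float(np.clip(weights[i], -0.999999, 0.999999)) for i in keep}
    return PcorNetwork(edges=edges, provenance=provenance)


def prune(general: PcorNetwork, specific: PcorNetwork, provenance: str | None = None) -> PcorNetwork:
    """Remove from ``general`` every edge also present in ``specific``.

    Edges are matched by unordered node pair only — weights and signs are
    ignored.  Surviving edges keep their weights from ``general``; the node
    set is recomputed from the surviving edges.
    """
    spec_edges = specific.edge_set()
    edges = {pair: w for pair, w in general.edges.items() if pair not in spec_edges}
    return PcorNetwork(
        edges=edges,
        provenance=provenance or f"{general.provenance} \\ {specific.provenance}",
    )


# ---------------------------------------------------------------------------
# disease-specific and patient-specific stages
# ---------------------------------------------------------------------------


@dataclass
class NetworkConfig:
    """Edge rule and pruning parameters for the network stage.

    The default is the absolute rule at tau=0.2: at the study's sample
    sizes a quantile rule forces every regime to keep the same edge count,
    so removing one patient swaps a fixed number of borderline noise edges
    in and out and the leave-one-out signatures are threshold churn rather
    than biology.  An absolute threshold leaves networks stable under
    leave-one-out except where a patient genuinely moves an edge across
    the detection boundary.  ``prune_leniency`` relaxes the edge rule
    (tau -> leniency * tau, or q -> q / leniency) for the *control* network
    when it is used as the pruning reference, so weakly detected control
    edges are not mistaken for disease-specific ones.
    """

    edge_rule: str = "absolute"
    q: float = 0.05
    tau: float = 0.15
    shrinkage: str | float = "analytic"
    prune_leniency: float = 0.5
    min_signature_fraction: float = 0.3  # consensus membership threshold

    def lenient(self) -> "NetworkConfig":
        out = NetworkConfig(**{**self.__dict__})
        if self.edge_rule == "absolute":
            out.tau = self.tau * self.prune_leniency
        else:
            out.q = min(0.999, self.q / self.prune_leniency)
        return out


@dataclass
class SignatureSet:
    """Per-patient signatures plus the deduplicated non-empty list."""

    per_patient: dict  # patient_id -> sorted list of metabolites
    signatures: list = field(default_factory=list)  # deduplicated, non-empty

    @classmethod
    def from_per_patient(cls, per_patient: dict) -> "SignatureSet":
        seen, dedup = set(), []
        for pid in per_patient:  # metadata order
            sig = tuple(per_patient[pid])
            if sig and sig not in seen:
                seen.add(sig)
                dedup.append(list(sig))
        return cls(per_patient=per_patient, signatures=dedup)

    @property
    def n_signatures(self) -> int:
        return len(self.signatures)


@dataclass
class ConsensusSignature:
    members: list            # consensus metabolite ids (sorted)
    frequency: dict          # metabolite -> count across retained signatures
    n_signatures: int
    fraction: float


def _network_for(matrix: MetaboliteMatrix, ids: list, cfg: NetworkConfig, provenance: str) -> PcorNetwork:
    pcor, _ = estimate_pcor(matrix.data.loc[ids], shrinkage=cfg.shrinkage)
    return build_network(pcor, cfg.edge_rule, cfg.q, cfg.tau, provenance=provenance)


def _shared_shrinkage(matrix: MetaboliteMatrix, meta: SampleMetadata, cfg: NetworkConfig) -> NetworkConfig:
    """Resolve 'analytic' shrinkage to one intensity shared by all regimes.

    Pruning compares edge sets across regimes with different sample sizes;
    a per-regime analytic lambda would put their partial correlations on
    different scales (the n=60 control regime shrinks far harder than the
    combined one), so the intensity is estimated once on all samples and
    reused everywhere.
    """
    if cfg.shrinkage != "analytic":
        return cfg
    ids = meta.ids_of("control") + meta.ids_of("fabry")
    lam = shrinkage_lambda(matrix.data.loc[ids].to_numpy(dtype=float))
    out = NetworkConfig(**{**cfg.__dict__})
    out.shrinkage = lam
    return out


def control_network(
    matrix: MetaboliteMatrix,
    meta: SampleMetadata,
    cfg: NetworkConfig | None = None,
    for_pruning: bool = False,
) -> PcorNetwork:
    cfg = cfg or NetworkConfig()
    if for_pruning:
        cfg = cfg.lenient()
    return _network_for(matrix, meta.ids_of("control"), cfg, "control")


def disease_plus_control_network(
    matrix: MetaboliteMatrix, meta: SampleMetadata, cfg: NetworkConfig | None = None
) -> PcorNetwork:
    cfg = cfg or NetworkConfig()
    ids = meta.ids_of("control") + meta.ids_of("fabry")
    return _network_for(matrix, ids, cfg, "disease_plus_control")


def disease_specific_network(
    matrix: MetaboliteMatrix,
    meta: SampleMetadata,
    cfg: NetworkConfig | None = None,
    _control_net: PcorNetwork | None = None,
) -> PcorNetwork:
    """Prune the "disease + control" network by the "control" network,
    keeping only disease-specific edges."""
    cfg = _shared_shrinkage(matrix, meta, cfg or NetworkConfig())
    if not meta.ids_of("control") or not meta.ids_of("fabry"):
        raise ValueError("both groups must be present")
    ctrl = _control_net if _control_net is not None else control_network(matrix, meta, cfg, for_pruning=True)
    both = disease_plus_control_network(matrix, meta, cfg)
    return prune(both, ctrl, provenance="disease_specific")


def patient_specific_signatures(
    matrix: MetaboliteMatrix, meta: SampleMetadata, cfg: NetworkConfig | None = None
) -> SignatureSet:
    """Leave-one-patient-out signatures.

    For each patient i: build the network of controls + patients-minus-i,
    prune it by the control network, then by the full disease-specific
    network; the signature is the node set of what survives — the disease
    edges whose detection depends on patient i.  Deterministic and
    independent of patient iteration order.
    """
    cfg = _shared_shrinkage(matrix, meta, cfg or NetworkConfig())
    ctrl_ids = meta.ids_of("control")
    fabry_ids = meta.ids_of("fabry")
    if len(fabry_ids) < 3:
        raise ValueError("need at least 3 patient samples for leave-one-out signatures")
    ctrl_net = control_network(matrix, meta, cfg, for_pruning=True)
    disease_net = disease_specific_network(matrix, meta, cfg, _control_net=ctrl_net)
    per_patient = {}
    for pid in fabry_ids:
        loo_ids = ctrl_ids + [f for f in fabry_ids if f != pid]
        loo_net = _network_for(matrix, loo_ids, cfg, provenance=f"loo:{pid}")
        minus_ctrl = prune(loo_net, ctrl_net, provenance=f"disease_specific_minus:{pid}")
        patient_net = prune(minus_ctrl, disease_net, provenance=f"patient_specific:{pid}")
        per_patient[pid] = sorted(patient_net.nodes)
    return SignatureSet.from_per_patient(per_patient)


def consensus_signature(
    signatures: SignatureSet, fraction: float = 1.0, fallback_to_top: bool = False
) -> ConsensusSignature:
    """Metabolites present in (at least a ``fraction`` of) all retained
    signatures; the full frequency table is always reported.

    With ``fallback_to_top``, an empty consensus falls back to the most
    redundant metabolites (those at the maximum observed frequency), so a
    downstream classifier always has a candidate signature.
    """
    sigs = signatures.signatures
    if not sigs:
        raise ValueError(
            "all patient signatures are empty; relax the edge rule (larger q "
            "or smaller tau) to retain more edges"
        )
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    freq: dict = {}
    for sig in sigs:
        for m in sig:
            freq[m] = freq.get(m, 0) + 1
    need = fraction * len(sigs)
    members = sorted(m for m, c in freq.items() if c >= need)
    if not members and fallback_to_top:
        top = max(freq.values())
        members = sorted(m for m, c in freq.items() if c == top)
    return ConsensusSignature(
        members=members,
        frequency=dict(sorted(freq.items())),
        n_signatures=len(sigs),
        fraction=fraction,
    )
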