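"""Seeded synthetic reaction datasets with the structure the pipeline assumes.

The generator emulates a gas-phase CHNO reaction dataset: small molecules
(2-7 heavy atoms of C/N/O plus hydrogens), mostly unimolecular
rearrangements, a low-level barrier height per reaction, and a high-level
reference barrier equal to the low-level one plus a ground-truth correction.
The default correction is a documented linear function of five descriptors
the feature pipeline can see (low-level barrier, TS Koopmans hardness, TS
weighted Laplacian gap, formed-CH and broken-CH counts) plus Gaussian
noise, so the asymptotic MAE floor of any regressor is
``noise_sd * sqrt(2/pi)`` and parameter recovery is quantifiable.

Scalars (energies, frequencies, orbital energies, bond orders) are
statistical stand-ins drawn from documented distributions — the generator
makes no attempt at chemically realistic potential-energy surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from scipy.optimize import minimize

from .bonds import bond_changes
from .constants import CM1_TO_KCAL, COVALENT_RADII, SYMBOLS, VALENCES
from .curation import RawRecord
from .geometry import Geometry
from .molgraph import (
    MolecularGraph,
    build_graph,
    spectrum_fingerprint,
    weighted_adjacency,
    weighted_fingerprint,
)
from .sqm import ReactionRecord, SQMSpecies, koopmans
from .topo import spectral_gap

HEAVY_ELEMENTS = ("C", "N", "O")

# Ground-truth correction: delta = intercept + sum(coef * descriptor) + noise.
# All five descriptors are visible to the models through the feature matrix.
DEFAULT_COEFFS: dict[str, float] = {
    "pm7.bh_pm7": 0.10,
    "pm7.eta_ts": 0.60,
    "topol.lambda1": 1.50,
    "bonds.+CH": 0.80,
    "bonds.-CH": -0.70,
}
DEFAULT_INTERCEPT = -2.0


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study conditions.

    noise_sd is the kcal/mol standard deviation of the irreducible part of
    the correction; failure_fractions plant curation discards with exact
    counts (round(fraction * n) records per reason).
    """

    n_reactions: int = 500
    seed: int = 0
    heavy_atom_range: tuple[int, int] = (2, 7)
    noise_sd: float = 2.0
    correction_spec: str = "default_linear"
    failure_fractions: dict[str, float] = field(default_factory=dict)
    ring_probability: float = 0.3
    n_edits_range: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        total = sum(self.failure_fractions.values())
        if not (0.0 <= total <= 1.0) or any(
            f < 0 for f in self.failure_fractions.values()
        ):
            raise ValueError("failure fractions must be in [0,1] and sum <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


# ---------------------------------------------------------------------------
# Random valence-respecting graphs
# ---------------------------------------------------------------------------

def _random_graph(cfg: GeneratorConfig, rng: np.random.Generator) -> MolecularGraph:
    """Connected heavy-atom skeleton with hydrogens saturating free valence."""
    lo, hi = cfg.heavy_atom_range
    n_heavy = int(rng.integers(lo, hi + 1))
    heavy = [HEAVY_ELEMENTS[i] for i in rng.integers(0, len(HEAVY_ELEMENTS), n_heavy)]
    cap = np.array([VALENCES[s] for s in heavy])
    adj = np.zeros((n_heavy, n_heavy), dtype=int)
    # random spanning tree respecting valence
    order = rng.permutation(n_heavy)
    placed = [order[0]]
    for v in order[1:]:
        choices = [u for u in placed if cap[u] - adj[u].sum() > 0]
        if not choices:  # all saturated (e.g. chain of O) -> retry
            return _random_graph(cfg, rng)
        u = choices[int(rng.integers(len(choices)))]
        adj[u, v] = adj[v, u] = 1
        placed.append(v)
    # optional single ring closure
    if n_heavy >= 3 and rng.random() < cfg.ring_probability:
        free = [i for i in range(n_heavy) if cap[i] - adj[i].sum() > 0]
        pairs = [
            (i, j)
            for i in free
            for j in free
            if i < j and adj[i, j] == 0
        ]
        if pairs:
            i, j = pairs[int(rng.integers(len(pairs)))]
            adj[i, j] = adj[j, i] = 1
    # hydrogens fill the remaining valence
    symbols = list(heavy)
    rows = [list(r) for r in adj]
    for i in range(n_heavy):
        for _ in range(cap[i] - adj[i].sum()):
            symbols.append("H")
            for r in rows:
                r.append(0)
            rows.append([0] * len(symbols))
            rows[i][-1] = rows[-1][i] = 1
    full = np.array(rows, dtype=int)
    z = np.array([{"H": 1, "C": 6, "N": 7, "O": 8}[s] for s in symbols])
    return MolecularGraph(full, z)


def _edge_swap(
    g: MolecularGraph, rng: np.random.Generator, max_tries: int = 50
) -> MolecularGraph | None:
    """One degree-preserving double-edge swap; None if no legal move found."""
    edges = g.edges()
    adj = g.adjacency.copy()
    for _ in range(max_tries):
        (a, b) = edges[int(rng.integers(len(edges)))]
        (c, d) = edges[int(rng.integers(len(edges)))]
        if len({a, b, c, d}) < 4:
            continue
        if rng.random() < 0.5:
            c, d = d, c
        # rewire (a,b),(c,d) -> (a,c),(b,d)
        if adj[a, c] or adj[b, d]:
            continue
        new = adj.copy()
        new[a, b] = new[b, a] = new[c, d] = new[d, c] = 0
        new[a, c] = new[c, a] = new[b, d] = new[d, b] = 1
        return MolecularGraph(new, g.atomic_numbers)
    return None


def _perturb_connectivity(
    g: MolecularGraph,
    rng: np.random.Generator,
    avoid: list[MolecularGraph],
    tol: float = 1e-3,
) -> MolecularGraph:
    """A degree-preserving rewiring spectrally distinct from every ``avoid`` graph."""
    avoid_fps = [spectrum_fingerprint(a) for a in avoid]

    def distinct(cand: MolecularGraph) -> bool:
        fp = spectrum_fingerprint(cand)
        return all(np.max(np.abs(fp - a)) > tol for a in avoid_fps)

    for _ in range(100):
        cand = _edge_swap(g, rng)
        if cand is not None and distinct(cand):
            return cand
    # small/star-like graphs admit no double-edge swap: move one bond instead
    n = g.n_atoms
    for _ in range(200):
        edges = g.edges()
        i, j = edges[int(rng.integers(len(edges)))]
        non = [
            (k, l)
            for k in range(n)
            for l in range(k + 1, n)
            if g.adjacency[k, l] == 0 and (k, l) != (i, j)
        ]
        if not non:
            continue
        k, l = non[int(rng.integers(len(non)))]
        adj = g.adjacency.copy()
        adj[i, j] = adj[j, i] = 0
        adj[k, l] = adj[l, k] = 1
        cand = MolecularGraph(adj, g.atomic_numbers)
        if distinct(cand):
            return cand
    raise RuntimeError("could not construct a distinct rewired graph")


# ---------------------------------------------------------------------------
# 3D embedding
# ---------------------------------------------------------------------------

def _radii(g: MolecularGraph) -> np.ndarray:
    return np.array([COVALENT_RADII[SYMBOLS[int(z)]] for z in g.atomic_numbers])


def _embed_energy(x: np.ndarray, bonded: np.ndarray, r0: np.ndarray, dmin: np.ndarray):
    n = r0.shape[0]
    coords = x.reshape(n, 3)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1) + 1e-12)
    iu = np.triu_indices(n, 1)
    # bonded springs toward covalent-radius sums
    db = d[iu] - r0[iu]
    eb = np.where(bonded[iu], db**2, 0.0)
    # non-bonded soft-core repulsion below the separation floor
    viol = np.minimum(d[iu] - dmin[iu], 0.0)
    enb = np.where(~bonded[iu], 4.0 * viol**2, 0.0)
    energy = eb.sum() + enb.sum()
    # gradient
    gmag = np.zeros_like(d)
    gmag[iu] = np.where(bonded[iu], 2.0 * db, 8.0 * viol)
    gmag = gmag + gmag.T
    with np.errstate(invalid="ignore"):
        grad = (gmag[:, :, None] * diff / d[:, :, None]).sum(axis=1)
    return energy, grad.ravel()


def _bfs_init(g: MolecularGraph, r0sum: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = g.n_atoms
    coords = np.zeros((n, 3))
    seen = np.zeros(n, dtype=bool)
    comps_offset = 0.0
    for root in range(n):
        if seen[root]:
            continue
        coords[root] = np.array([comps_offset, 0.0, 0.0])
        seen[root] = True
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v in np.nonzero(g.adjacency[u])[0]:
                if seen[v]:
                    continue
                for _ in range(20):
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    cand = coords[u] + r0sum[u, v] * direction
                    if not seen.any() or np.all(
                        np.linalg.norm(coords[seen] - cand, axis=1) > 0.8
                    ):
                        break
                coords[v] = cand
                seen[v] = True
                queue.append(v)
        comps_offset += 8.0  # keep disconnected fragments far apart
    return coords


def embed_graph(
    g: MolecularGraph,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
    max_tries: int = 8,
) -> Geometry | None:
    """3D coordinates whose distance-based bond perception reproduces ``g``.

    Bonded pairs are relaxed to the covalent-radius sum, non-bonded pairs
    pushed beyond 1.45x that sum (safely outside the 1.2x detection cutoff).
    Returns None when no satisfying embedding is found.
    """
    radii = _radii(g)
    r0 = radii[:, None] + radii[None, :]
    bonded = g.adjacency.astype(bool)
    dmin = 1.45 * r0
    symbols = g.symbols()
    for attempt in range(max_tries):
        if init is not None and attempt == 0:
            x0 = np.asarray(init, dtype=float).ravel()
        else:
            x0 = _bfs_init(g, r0, rng).ravel()
        res = minimize(
            _embed_energy,
            x0,
            args=(bonded, r0, dmin),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 300},
        )
        coords = res.x.reshape(-1, 3)
        geom = Geometry(symbols, coords)
        d = geom.distance_matrix()
        n = g.n_atoms
        iu = np.triu_indices(n, 1)
        ok_b = np.all(d[iu][bonded[iu]] <= 1.15 * r0[iu][bonded[iu]])
        ok_nb = np.all(d[iu][~bonded[iu]] >= 1.3 * r0[iu][~bonded[iu]])
        if ok_b and ok_nb:
            return geom
    return None


def graph_to_smiles(g: MolecularGraph) -> str:
    """SMILES with explicit hydrogens (radical centers preserved)."""
    mol = Chem.RWMol()
    for z in g.atomic_numbers:
        atom = Chem.Atom(int(z))
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    for i, j in g.edges():
        mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return Chem.MolToSmiles(m)


# ---------------------------------------------------------------------------
# Species and reactions
# ---------------------------------------------------------------------------

def gen_species(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[Geometry, MolecularGraph, SQMSpecies, str]:
    """One random species: geometry, graph, low-level scalars, SMILES."""
    for _ in range(50):
        graph = _random_graph(cfg, rng)
        geom = embed_graph(graph, rng)
        if geom is not None:
            break
    else:
        raise RuntimeError("species embedding failed repeatedly")
    species = _draw_scalars(graph, rng, ts=False)
    return geom, graph, species, graph_to_smiles(graph)


def _draw_scalars(
    g: MolecularGraph, rng: np.random.Generator, ts: bool
) -> SQMSpecies:
    n = g.n_atoms
    n_modes = max(3 * n - 6, 1)
    pos = rng.uniform(200.0, 3500.0, size=n_modes - (1 if ts else 0))
    freqs = np.sort(pos)
    if ts:
        freqs = np.concatenate(([-rng.uniform(400.0, 2000.0)], freqs))
    zpe = 0.5 * freqs[freqs > 0].sum() * CM1_TO_KCAL
    homo = rng.normal(-9.5, 0.8)
    gap = rng.uniform(1.0, 8.0) if ts else rng.uniform(6.0, 12.0)
    # bond orders ~1 on bonds with mild noise
    noise = rng.normal(0.0, 0.03, size=(n, n))
    bo = g.adjacency * (1.0 + 0.5 * (noise + noise.T))
    return SQMSpecies(
        energy=rng.normal(0.0, 20.0),
        zpe=zpe,
        frequencies=freqs,
        homo=homo,
        lumo=homo + gap,
        bond_orders=bo,
        self_polarizability=rng.normal(-0.8 * n, 0.5),
    )


def _ts_bond_orders(
    reactant: MolecularGraph, product: MolecularGraph, rng: np.random.Generator
) -> np.ndarray:
    """Partial bond orders at the TS: changing bonds sit near one half."""
    n = reactant.n_atoms
    noise = rng.normal(0.0, 0.02, size=(n, n))
    bo = 0.5 * (reactant.adjacency + product.adjacency).astype(float)
    return bo * (1.0 + noise + noise.T)


def _declash(coords: np.ndarray, min_d: float = 0.7, max_iter: int = 200) -> np.ndarray:
    """Push overlapping atom pairs apart until every distance exceeds min_d."""
    coords = coords.copy()
    n = len(coords)
    for _ in range(max_iter):
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= min_d:
            break
        axis = diff[i, j]
        norm = np.linalg.norm(axis)
        axis = axis / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
        shift = 0.5 * (min_d - d[i, j]) + 0.05
        coords[i] += shift * axis
        coords[j] -= shift * axis
    return coords


def _ts_geometry(
    geom_r: Geometry, geom_p: Geometry, rng: np.random.Generator, union: MolecularGraph
) -> Geometry:
    for t in (0.5, 0.45, 0.55, 0.4, 0.6):
        coords = (1 - t) * geom_r.coords + t * geom_p.coords
        d = Geometry(geom_r.symbols, coords).distance_matrix()
        off = ~np.eye(len(coords), dtype=bool)
        if d[off].min() > 0.6:
            return Geometry(geom_r.symbols, coords)
    # midpoint collapsed somewhere: resolve the clash geometrically
    coords = _declash(0.5 * (geom_r.coords + geom_p.coords))
    return Geometry(geom_r.symbols, coords)


def _truth_descriptors(
    record_parts: dict, rng: np.random.Generator
) -> dict[str, float]:
    """The five visible descriptors the default correction is linear in."""
    g_ts = build_graph(record_parts["geom_ts"])
    lam1 = spectral_gap(weighted_adjacency(record_parts["geom_ts"], g_ts))
    eta, _ = koopmans(record_parts["ts"].homo, record_parts["ts"].lumo)
    changes = bond_changes(record_parts["graph_r"], record_parts["graph_p"])
    return {
        "pm7.bh_pm7": record_parts["bh_pm7"],
        "pm7.eta_ts": eta,
        "topol.lambda1": lam1,
        "bonds.+CH": float(changes["+CH"]),
        "bonds.-CH": float(changes["-CH"]),
    }


def correction_value(
    descriptors: dict[str, float],
    spec: str,
    rng: np.random.Generator,
) -> float:
    """Noise-free ground-truth correction for one reaction."""
    if spec == "default_linear":
        return DEFAULT_INTERCEPT + sum(
            c * descriptors[k] for k, c in DEFAULT_COEFFS.items()
        )
    if spec == "hidden_driver":
        # half the signal rides on a latent variable no feature encodes,
        # to probe graceful degradation
        visible = DEFAULT_INTERCEPT + sum(
            c * descriptors[k] for k, c in DEFAULT_COEFFS.items()
        )
        return visible + 2.0 * rng.normal()
    raise ValueError(f"unknown correction_spec {spec!r}")


def gen_reaction(
    cfg: GeneratorConfig, rng: np.random.Generator, record_id: str = ""
) -> tuple[ReactionRecord, RawRecord, float]:
    """One reaction: curated record, raw curation inputs, true noiseless delta."""
    for _ in range(50):
        geom_r, graph_r, sp_r, smi_r = gen_species(cfg, rng)
        # product: 1-3 degree-preserving rewirings, spectrally distinct
        n_edits = int(rng.integers(cfg.n_edits_range[0], cfg.n_edits_range[1] + 1))
        graph_p = graph_r
        for _ in range(n_edits):
            nxt = _edge_swap(graph_p, rng)
            if nxt is not None:
                graph_p = nxt
        fp_r = spectrum_fingerprint(graph_r)
        if np.max(np.abs(spectrum_fingerprint(graph_p) - fp_r)) <= 1e-3:
            continue
        geom_p = embed_graph(graph_p, rng, init=geom_r.coords)
        if geom_p is None:
            continue
        break
    else:
        raise RuntimeError("reaction generation failed repeatedly")

    union = MolecularGraph(
        ((graph_r.adjacency + graph_p.adjacency) > 0).astype(int),
        graph_r.atomic_numbers,
    )
    geom_ts = _ts_geometry(geom_r, geom_p, rng, union)

    sp_p = _draw_scalars(graph_p, rng, ts=False)
    sp_ts = _draw_scalars(union, rng, ts=True)
    sp_ts.bond_orders = _ts_bond_orders(graph_r, graph_p, rng)

    # set the low-level barrier by construction
    bh_pm7 = rng.uniform(5.0, 60.0)
    sp_ts.energy = sp_r.energy + sp_r.zpe + bh_pm7 - sp_ts.zpe
    sp_p.energy = sp_r.energy + rng.normal(0.0, 15.0)

    parts = {
        "geom_ts": geom_ts,
        "ts": sp_ts,
        "graph_r": graph_r,
        "graph_p": graph_p,
        "bh_pm7": bh_pm7,
    }
    delta_true = correction_value(_truth_descriptors(parts, rng), cfg.correction_spec, rng)
    noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
    bh_dft = bh_pm7 + delta_true + noise

    record = ReactionRecord(
        reactant=sp_r,
        ts=sp_ts,
        product=sp_p,
        geom_reactant=geom_r,
        geom_ts=geom_ts,
        geom_product=geom_p,
        smiles_reactant=smi_r,
        smiles_product=graph_to_smiles(graph_p),
        bh_dft=bh_dft,
        record_id=record_id,
    )
    raw = RawRecord(
        dft_reactant=geom_r,
        dft_product=geom_p,
        ts_opt_ok=True,
        irc_fwd_endpoint=geom_r,
        irc_rev_endpoint=geom_p,
        opt_endpoint_fwd=geom_r,
        opt_endpoint_rev=geom_p,
        opt_dataset_reactant=geom_r,
        opt_dataset_product=geom_p,
        record_id=record_id,
    )
    return record, raw, delta_true


def _plant_failure(
    raw: RawRecord,
    record: ReactionRecord,
    kind: str,
    rng: np.random.Generator,
) -> RawRecord:
    if kind == "ts_opt_failed":
        return replace(raw, ts_opt_ok=False)
    graph_r = build_graph(record.geom_reactant)
    graph_p = build_graph(record.geom_product)
    if kind == "connectivity_mismatch":
        bad = _perturb_connectivity(graph_r, rng, avoid=[graph_r, graph_p])
        geom_bad = embed_graph(bad, rng)
        if geom_bad is None:
            raise RuntimeError("failed to embed rewired endpoint")
        return replace(raw, irc_fwd_endpoint=geom_bad, opt_endpoint_fwd=geom_bad)
    if kind == "conformation_mismatch":
        # re-embed the same connectivity from a fresh start: a different
        # conformer, identical adjacency fingerprint
        for _ in range(20):
            geom_alt = embed_graph(graph_r, rng)
            if geom_alt is None:
                continue
            if (
                np.max(
                    np.abs(
                        weighted_fingerprint(geom_alt)
                        - weighted_fingerprint(record.geom_reactant)
                    )
                )
                > 5e-3
            ):
                return replace(raw, opt_endpoint_fwd=geom_alt)
        raise RuntimeError("failed to construct an alternative conformer")
    raise ValueError(f"unknown failure kind {kind!r}")


def gen_dataset(
    cfg: GeneratorConfig,
) -> tuple[list[ReactionRecord], list[RawRecord], dict]:
    """Full seeded dataset plus a truth sidecar.

    Returns curated-ready reaction records, raw curation inputs (with planted
    failures at exact counts round(fraction * n)), and a dict with the
    noise-free deltas, the planted failure labels and the correction spec.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reactions
    labels = ["ok"] * n
    pos = 0
    for kind, frac in cfg.failure_fractions.items():
        count = int(round(frac * n))
        for _ in range(count):
            labels[pos] = kind
            pos += 1
    perm = rng.permutation(n)
    labels = [labels[i] for i in perm]

    records: list[ReactionRecord] = []
    raws: list[RawRecord] = []
    deltas: list[float] = []
    for i in range(n):
        record, raw, delta = gen_reaction(cfg, rng, record_id=f"rxn{i:05d}")
        if labels[i] != "ok":
            raw = _plant_failure(raw, record, labels[i], rng)
        records.append(record)
        raws.append(raw)
        deltas.append(delta)
    truth = {
        "delta_true": np.array(deltas),
        "labels": labels,
        "correction_spec": cfg.correction_spec,
        "coefficients": dict(DEFAULT_COEFFS),
        "intercept": DEFAULT_INTERCEPT,
        "noise_sd": cfg.noise_sd,
    }
    return records, raws, truth
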