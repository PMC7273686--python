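"""Core data types and readers/writers.

The in-memory model is deliberately small: an :class:`AbundanceTable` wraps an
ESV-by-sample integer count matrix plus per-sample environment labels, a
taxonomy map is a plain ``dict`` from ESV id to a ranked lineage tuple, and a
:class:`CooccurrenceNetwork` wraps a :class:`networkx.Graph` whose edges carry
the full significance record (scores, per-measure / merged / adjusted
p-values, sign, and the set of environments supporting the edge).

Supported on-disk formats: TSV count tables (first column ESV id, header row
sample ids), BIOM v2.1 HDF5 tables, TSV metadata (sample_id, environment),
TSV taxonomy, GraphML and edge-list TSV for networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

TAXONOMIC_RANKS = ("domain", "phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"

#: canonical per-edge attribute names, in edge-TSV column order
EDGE_FIELDS = ("sign", "rho", "bc_sim", "p_spearman", "p_bc", "p_merged", "p_adjusted")

EDGE_TSV_COLUMNS = (
    "esv_a",
    "esv_b",
    "sign",
    "rho",
    "bc_similarity",
    "p_spearman",
    "p_bc",
    "p_merged",
    "p_adjusted",
    "environments",
)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered ESV pair: lexicographically sorted, no self-loops."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class AbundanceTable:
    """ESV-by-sample non-negative integer count matrix with environment labels.

    Parameters
    ----------
    esv_ids
        Row identifiers (opaque strings, unique).
    sample_ids
        Column identifiers (opaque strings, unique).
    counts
        ``(n_esvs, n_samples)`` array of non-negative integers.
    environment_of
        Map ``sample_id -> environment label``; may be empty (no labels yet)
        but when non-empty must cover every sample exactly once.
    """

    esv_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    environment_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.esv_ids = [str(e) for e in self.esv_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()
        self.counts = self.counts.astype(np.int64, copy=False)

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, m = len(self.esv_ids), len(self.sample_ids)
        if self.counts.shape != (n, m):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{n} ESV ids x {m} sample ids"
            )
        if len(set(self.esv_ids)) != n:
            raise ValueError("duplicate ESV ids")
        if len(set(self.sample_ids)) != m:
            raise ValueError("duplicate sample ids")
        if self.counts.size:
            if not np.issubdtype(self.counts.dtype, np.number):
                raise ValueError("counts must be numeric")
            if np.any(self.counts < 0):
                raise ValueError("negative counts")
            if not np.issubdtype(self.counts.dtype, np.integer):
                if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                    raise ValueError("non-integer counts")
        if self.environment_of:
            missing = [s for s in self.sample_ids if s not in self.environment_of]
            if missing:
                raise ValueError(f"samples without environment label: {missing[:5]}")

    # -- convenience ------------------------------------------------------
    @property
    def n_esvs(self) -> int:
        return len(self.esv_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances (columns sum to 1; all-zero columns stay 0)."""
        totals = self.counts.sum(axis=0, dtype=float)
        safe = np.where(totals > 0, totals, 1.0)
        return self.counts / safe

    def mean_relative_abundance(self) -> dict[str, float]:
        rel = self.relative_abundance()
        return dict(zip(self.esv_ids, rel.mean(axis=1) if rel.size else []))

    def subset_esvs(self, keep: Sequence[str]) -> "AbundanceTable":
        index = {e: i for i, e in enumerate(self.esv_ids)}
        rows = [index[e] for e in keep]
        return AbundanceTable(
            list(keep), list(self.sample_ids), self.counts[rows, :],
            dict(self.environment_of),
        )

    def subset_samples(self, keep: Sequence[str]) -> "AbundanceTable":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in keep]
        env = {s: self.environment_of[s] for s in keep if s in self.environment_of}
        return AbundanceTable(list(self.esv_ids), list(keep), self.counts[:, cols], env)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.esv_ids == other.esv_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and self.environment_of == other.environment_of
        )


# ---------------------------------------------------------------------------
# abundance table I/O
# ---------------------------------------------------------------------------

def read_abundance_table(path: str | Path, format: str = "tsv") -> AbundanceTable:
    """Read a count table from TSV or BIOM v2.1 HDF5.

    TSV dialect: UTF-8, tab-separated, header row of sample ids, first column
    ESV ids, integer cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv_table(path)
    if format == "biom-hdf5":
        return _read_biom_hdf5(path)
    raise ValueError(f"unknown abundance table format: {format!r}")


def _read_tsv_table(path: Path) -> AbundanceTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed TSV abundance table {path}: {exc}") from exc
    if df.empty and df.columns.size == 0 and df.index.size == 0:
        return AbundanceTable([], [], np.zeros((0, 0), dtype=np.int64))
    counts = np.zeros(df.shape, dtype=np.int64)
    for i, (esv, row) in enumerate(df.iterrows()):
        for j, value in enumerate(row):
            try:
                x = int(value)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-integer count {value!r} at ESV {esv!r}, "
                    f"sample {df.columns[j]!r} (row {i + 2})"
                ) from None
            if x < 0:
                raise ValueError(
                    f"{path}: negative count {x} at ESV {esv!r}, "
                    f"sample {df.columns[j]!r} (row {i + 2})"
                )
            counts[i, j] = x
    return AbundanceTable(list(df.index), list(df.columns), counts)


def _read_biom_hdf5(path: Path) -> AbundanceTable:
    """Read the BIOM 2.1 HDF5 layout (observation-major CSR or sample-major CSC)."""
    with h5py.File(path, "r") as h5:
        esv_ids = [x.decode() if isinstance(x, bytes) else str(x)
                   for x in h5["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x)
                      for x in h5["sample/ids"][:]]
        shape = (len(esv_ids), len(sample_ids))
        if "observation/matrix/data" in h5:
            grp = h5["observation/matrix"]
            mat = sp.csr_matrix(
                (grp["data"][:], grp["indices"][:], grp["indptr"][:]), shape=shape
            )
        elif "sample/matrix/data" in h5:
            grp = h5["sample/matrix"]
            mat = sp.csc_matrix(
                (grp["data"][:], grp["indices"][:], grp["indptr"][:]), shape=shape
            )
        else:
            raise ValueError(f"{path}: no BIOM matrix group found")
    dense = np.asarray(mat.todense())
    if np.any(dense < 0) or not np.all(np.equal(np.mod(dense, 1), 0)):
        raise ValueError(f"{path}: BIOM matrix has negative or non-integer counts")
    return AbundanceTable(esv_ids, sample_ids, dense.astype(np.int64))


def write_abundance_table(table: AbundanceTable, path: str | Path,
                          format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(table.counts, index=table.esv_ids, columns=table.sample_ids)
        df.index.name = "esv_id"
        df.to_csv(path, sep="\t")
    elif format == "biom-hdf5":
        _write_biom_hdf5(table, path)
    else:
        raise ValueError(f"unknown abundance table format: {format!r}")


def _write_biom_hdf5(table: AbundanceTable, path: Path) -> None:
    csr = sp.csr_matrix(table.counts)
    csc = sp.csc_matrix(table.counts)
    with h5py.File(path, "w") as h5:
        h5.attrs["format-version"] = [2, 1]
        h5.attrs["type"] = "OTU table"
        h5.attrs["shape"] = list(table.counts.shape)
        h5.create_dataset("observation/ids",
                          data=np.array(table.esv_ids, dtype="S"))
        h5.create_dataset("sample/ids", data=np.array(table.sample_ids, dtype="S"))
        for name, mat in (("observation/matrix", csr), ("sample/matrix", csc)):
            h5.create_dataset(f"{name}/data", data=mat.data.astype(float))
            h5.create_dataset(f"{name}/indices", data=mat.indices.astype(np.int64))
            h5.create_dataset(f"{name}/indptr", data=mat.indptr.astype(np.int64))


def read_metadata(path: str | Path) -> dict[str, str]:
    """Read sample metadata TSV with columns ``sample_id`` and ``environment``.

    Duplicate rows with a consistent label are deduplicated; conflicting
    labels for one sample raise.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    cols = list(df.columns)
    if "sample_id" in cols and "environment" in cols:
        pairs = df[["sample_id", "environment"]].itertuples(index=False)
    elif len(cols) >= 2:
        pairs = df[cols[:2]].itertuples(index=False)
    else:
        raise ValueError(f"{path}: metadata needs sample_id and environment columns")
    out: dict[str, str] = {}
    for sample, env in pairs:
        sample, env = str(sample), str(env)
        if sample in out and out[sample] != env:
            raise ValueError(
                f"{path}: sample {sample!r} has conflicting environment labels "
                f"{out[sample]!r} and {env!r}"
            )
        out[sample] = env
    return out


def write_metadata(environment_of: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(
        {"sample_id": list(environment_of), "environment": list(environment_of.values())}
    )
    df.to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def read_taxonomy(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a taxonomy TSV: esv_id + one column per rank (coarse to fine).

    Missing ranks become explicit ``"unclassified"`` markers; lineages are
    padded/truncated to the six standard ranks (domain..genus).
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    out: dict[str, tuple[str, ...]] = {}
    value_cols = list(df.columns[1:])
    for _, row in df.iterrows():
        lineage = [
            str(row[c]) if pd.notna(row[c]) and str(row[c]).strip() else UNCLASSIFIED
            for c in value_cols
        ]
        lineage = (lineage + [UNCLASSIFIED] * len(TAXONOMIC_RANKS))[: len(TAXONOMIC_RANKS)]
        out[str(row.iloc[0])] = tuple(lineage)
    return out


def write_taxonomy(taxonomy: Mapping[str, Sequence[str]], path: str | Path) -> None:
    rows = {esv: list(lineage) for esv, lineage in taxonomy.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(TAXONOMIC_RANKS))
    df.index.name = "esv_id"
    df.to_csv(Path(path), sep="\t")


def rank_of(lineage: Sequence[str], rank: str) -> str:
    try:
        return lineage[TAXONOMIC_RANKS.index(rank)]
    except (ValueError, IndexError):
        return UNCLASSIFIED


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

@dataclass
class CooccurrenceNetwork:
    """A signed, attributed co-occurrence network.

    ``graph`` is an undirected :class:`networkx.Graph`; every edge carries the
    attributes in :data:`EDGE_FIELDS` plus ``environments`` (sorted tuple of
    environment labels supporting the edge).  Vertices carry ``taxonomy``
    (semicolon-joined lineage), ``mean_abundance`` and ``environments``.
    ``environment`` tags a single-environment subnetwork; it is ``None`` for
    merged networks.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    environment: str | None = None

    # -- construction -----------------------------------------------------
    def add_vertex(self, esv: str, taxonomy: str = UNCLASSIFIED,
                   mean_abundance: float = 0.0,
                   environments: tuple[str, ...] = ()) -> None:
        self.graph.add_node(esv, taxonomy=taxonomy,
                            mean_abundance=float(mean_abundance),
                            environments=tuple(environments))

    def add_edge(self, a: str, b: str, **attrs) -> None:
        a, b = canonical_pair(a, b)
        attrs.setdefault("environments", (self.environment,) if self.environment else ())
        attrs["environments"] = tuple(attrs["environments"])
        self.graph.add_edge(a, b, **attrs)

    # -- views ------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_keys(self) -> set[tuple[str, str]]:
        return {canonical_pair(a, b) for a, b in self.graph.edges}

    def finalize(self) -> "CooccurrenceNetwork":
        """Drop unconnected vertices (degree 0), in place; return self."""
        isolated = [v for v, d in self.graph.degree if d == 0]
        self.graph.remove_nodes_from(isolated)
        return self

    def validate(self) -> None:
        for a, b, data in self.graph.edges(data=True):
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            rho = data.get("rho")
            sign = data.get("sign")
            if rho is not None and sign is not None:
                if rho == 0 or int(np.sign(rho)) != int(sign):
                    raise ValueError(f"edge ({a},{b}): sign {sign} != sign of rho {rho}")

    def copy(self) -> "CooccurrenceNetwork":
        return CooccurrenceNetwork(self.graph.copy(), self.environment)


def _fmt(value) -> str:
    if value is None:
        return "nan"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_network(net: CooccurrenceNetwork, path: str | Path,
                  format: str = "edge-tsv") -> None:
    """Write a network as GraphML or edge-list TSV (deterministic row order)."""
    path = Path(path)
    if format == "edge-tsv":
        lines = ["\t".join(EDGE_TSV_COLUMNS)]
        for a, b in sorted(net.edge_keys()):
            d = net.graph.edges[a, b]
            lines.append("\t".join([
                a, b,
                _fmt(int(d.get("sign", 0))),
                _fmt(float(d.get("rho", np.nan))),
                _fmt(float(d.get("bc_sim", np.nan))),
                _fmt(float(d.get("p_spearman", np.nan))),
                _fmt(float(d.get("p_bc", np.nan))),
                _fmt(float(d.get("p_merged", np.nan))),
                _fmt(float(d.get("p_adjusted", np.nan))),
                ",".join(d.get("environments", ())),
            ]))
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        g = nx.Graph()
        for v in sorted(net.graph.nodes):
            d = net.graph.nodes[v]
            g.add_node(
                v,
                taxonomy=str(d.get("taxonomy", UNCLASSIFIED)),
                mean_abundance=float(d.get("mean_abundance", 0.0)),
                environments=",".join(d.get("environments", ())),
            )
        for a, b in sorted(net.edge_keys()):
            d = net.graph.edges[a, b]
            attrs = {
                "sign": int(d.get("sign", 0)),
                "rho": float(d.get("rho", np.nan)),
                "bc_sim": float(d.get("bc_sim", np.nan)),
                "p_spearman": float(d.get("p_spearman", np.nan)),
                "p_bc": float(d.get("p_bc", np.nan)),
                "p_merged": float(d.get("p_merged", np.nan)),
                "p_adjusted": float(d.get("p_adjusted", np.nan)),
                "environments": ",".join(d.get("environments", ())),
            }
            if "by_env" in d:
                attrs["by_env"] = json.dumps(d["by_env"], sort_keys=True)
            if "sign_discordant" in d:
                attrs["sign_discordant"] = bool(d["sign_discordant"])
            g.add_edge(a, b, **attrs)
        if net.environment is not None:
            g.graph["environment"] = net.environment
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path: str | Path, format: str = "edge-tsv") -> CooccurrenceNetwork:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edge-tsv":
        net = CooccurrenceNetwork()
        lines = path.read_text().splitlines()
        if not lines or lines[0].split("\t") != list(EDGE_TSV_COLUMNS):
            raise ValueError(f"{path}: bad edge-TSV header")
        for line in lines[1:]:
            if not line.strip():
                continue
            f = line.split("\t")
            a, b = f[0], f[1]
            for v in (a, b):
                if v not in net.graph:
                    net.add_vertex(v)
            net.add_edge(
                a, b,
                sign=int(f[2]), rho=float(f[3]), bc_sim=float(f[4]),
                p_spearman=float(f[5]), p_bc=float(f[6]), p_merged=float(f[7]),
                p_adjusted=float(f[8]),
                environments=tuple(x for x in f[9].split(",") if x),
            )
        return net
    if format == "graphml":
        g = nx.read_graphml(path)
        net = CooccurrenceNetwork(environment=g.graph.get("environment"))
        for v, d in g.nodes(data=True):
            net.add_vertex(
                v,
                taxonomy=d.get("taxonomy", UNCLASSIFIED),
                mean_abundance=float(d.get("mean_abundance", 0.0)),
                environments=tuple(x for x in d.get("environments", "").split(",") if x),
            )
        for a, b, d in g.edges(data=True):
            attrs = {
                "sign": int(d["sign"]),
                "rho": float(d["rho"]),
                "bc_sim": float(d["bc_sim"]),
                "p_spearman": float(d["p_spearman"]),
                "p_bc": float(d["p_bc"]),
                "p_merged": float(d["p_merged"]),
                "p_adjusted": float(d["p_adjusted"]),
                "environments": tuple(x for x in d.get("environments", "").split(",") if x),
            }
            if "by_env" in d:
                attrs["by_env"] = json.loads(d["by_env"])
            if "sign_discordant" in d:
                attrs["sign_discordant"] = bool(d["sign_discordant"])
            net.add_edge(a, b, **attrs)
        return net
    raise ValueError(f"unknown network format: {format!r}")


def merge_networks(nets: Iterable[CooccurrenceNetwork]) -> CooccurrenceNetwork:
    """Merge per-environment subnetworks into one network.

    Vertices are unioned; edges are unioned under canonical-pair equality.
    An edge shared by k inputs carries an environment set of size k and keeps
    its per-environment significance record in the ``by_env`` attribute.  The
    representative score/sign of a shared edge comes from the environment
    with the largest ``|rho|`` (ties broken by environment label); edges whose
    sign differs between environments are flagged ``sign_discordant``.
    Vertices left without any incident edge are dropped.
    """
    nets = list(nets)
    tags = [n.environment for n in nets]
    if any(t is None for t in tags):
        raise ValueError("every input network must carry an environment tag")
    if len(set(tags)) != len(tags):
        raise ValueError(f"duplicate environment tags among inputs: {tags}")

    merged = CooccurrenceNetwork()
    vertex_envs: dict[str, set[str]] = {}
    vertex_abund: dict[str, dict[str, float]] = {}
    vertex_tax: dict[str, str] = {}
    edge_records: dict[tuple[str, str], dict[str, dict]] = {}

    for net in nets:
        env = net.environment
        for v, d in net.graph.nodes(data=True):
            vertex_envs.setdefault(v, set()).add(env)
            vertex_abund.setdefault(v, {})[env] = float(d.get("mean_abundance", 0.0))
            if v not in vertex_tax or vertex_tax[v] == UNCLASSIFIED:
                vertex_tax[v] = str(d.get("taxonomy", UNCLASSIFIED))
        for a, b, d in net.graph.edges(data=True):
            key = canonical_pair(a, b)
            edge_records.setdefault(key, {})[env] = {
                f: d.get(f) for f in EDGE_FIELDS
            }

    for v in sorted(vertex_envs):
        abund = vertex_abund[v]
        merged.add_vertex(
            v,
            taxonomy=vertex_tax.get(v, UNCLASSIFIED),
            mean_abundance=float(np.mean(list(abund.values()))) if abund else 0.0,
            environments=tuple(sorted(vertex_envs[v])),
        )
    for (a, b), by_env in sorted(edge_records.items()):
        rep_env = max(by_env, key=lambda e: (abs(by_env[e].get("rho") or 0.0), e))
        rep = by_env[rep_env]
        signs = {r.get("sign") for r in by_env.values() if r.get("sign") is not None}
        merged.add_edge(
            a, b,
            **{f: rep.get(f) for f in EDGE_FIELDS},
            environments=tuple(sorted(by_env)),
            by_env=by_env,
            sign_discordant=len(signs) > 1,
        )
    return merged.finalize()
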