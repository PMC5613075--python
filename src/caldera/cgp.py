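"""Cartesian genetic programming over 32-input symbolic expressions.

A classifier is a symbolic mathematical expression encoded as a fixed 6 x 6
feed-forward grid of function nodes drawn from {add, sub, mul, div, mean,
min, max, abs}, wired to 32 terminal inputs (one per sample of a sliding
window, or one per spectral density bin).  Each node carries a function gene
and two connection genes; a single output gene selects the node (or
terminal) whose value is the expression output.  Nodes not reachable from
the output are inactive: they do not affect the phenotype but provide
neutral genetic variation, a standard and deliberate feature of CGP.

Connection genes address terminals (indices 0..31) or nodes in strictly
earlier columns (unlimited levels-back), so every genome is feed-forward by
construction.  Genomes are plain integer arrays; evaluation is vectorised
over batches of input rows, which is what makes evolving against tens of
thousands of sliding windows tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

#: Values are clamped to this magnitude after every node application so that
#: chained multiplications cannot overflow to inf (totality guarantee).
VALUE_CLAMP = 1e150

#: |denominator| below this triggers protected division (returns numerator).
DIV_EPS = 1e-6

FUNCTION_NAMES: Tuple[str, ...] = (
    "add", "sub", "mul", "div", "mean", "min", "max", "abs",
)

#: Number of connection genes each function actually reads ("abs" ignores b).
FUNCTION_ARITY: Dict[str, int] = {
    "add": 2, "sub": 2, "mul": 2, "div": 2,
    "mean": 2, "min": 2, "max": 2, "abs": 1,
}


@dataclass(frozen=True)
class CgpGeometry:
    """Grid shape and function set of a CGP genome.

    Defaults encode the deployed classifier family: up to 36 function
    instances on a 6 x 6 plane over 32 terminals.
    """

    rows: int = 6
    cols: int = 6
    n_inputs: int = 32
    functions: Tuple[str, ...] = FUNCTION_NAMES

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.n_inputs < 1:
            raise ValueError("geometry dimensions must be positive")
        unknown = set(self.functions) - set(FUNCTION_NAMES)
        if unknown:
            raise ValueError(f"unknown functions: {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def node_column(self, node_index: int) -> int:
        """Column of a node under column-major node numbering."""
        return node_index // self.rows

    def max_source(self, node_index: int) -> int:
        """Exclusive upper bound on connection-gene values for this node.

        A node may read any terminal or any node in a strictly earlier
        column (unlimited levels-back).
        """
        return self.n_inputs + self.node_column(node_index) * self.rows

    def __eq__(self, other) -> bool:  # frozen dataclass w/ tuple field
        return (
            isinstance(other, CgpGeometry)
            and (self.rows, self.cols, self.n_inputs, self.functions)
            == (other.rows, other.cols, other.n_inputs, other.functions)
        )

    def __hash__(self) -> int:
        return hash((self.rows, self.cols, self.n_inputs, self.functions))


DEFAULT_GEOMETRY = CgpGeometry()


@dataclass
class CgpGenome:
    """A CGP genotype: 36 (function, in_a, in_b) node triples + output gene.

    ``nodes`` is an int array of shape (n_nodes, 3).  Source indices <
    ``n_inputs`` address terminals; index ``n_inputs + j`` addresses node j.
    """

    nodes: np.ndarray
    output_gene: int
    geometry: CgpGeometry = field(default_factory=CgpGeometry)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=np.int64)
        self.output_gene = int(self.output_gene)
        if self.nodes.shape != (self.geometry.n_nodes, 3):
            raise ValueError("malformed genome: wrong node array shape")

    def validate(self) -> None:
        """Raise ValueError("malformed genome") on any out-of-range gene."""
        geo = self.geometry
        for j in range(geo.n_nodes):
            f, a, b = self.nodes[j]
            if not 0 <= f < len(geo.functions):
                raise ValueError(f"malformed genome: node {j} function id {f}")
            hi = geo.max_source(j)
            if not (0 <= a < hi and 0 <= b < hi):
                raise ValueError(f"malformed genome: node {j} source out of range")
        if not 0 <= self.output_gene < geo.n_inputs + geo.n_nodes:
            raise ValueError("malformed genome: output gene out of range")

    def copy(self) -> "CgpGenome":
        return CgpGenome(self.nodes.copy(), self.output_gene, self.geometry)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CgpGenome)
            and self.geometry == other.geometry
            and self.output_gene == other.output_gene
            and np.array_equal(self.nodes, other.nodes)
        )


def random_genome(geometry: CgpGeometry = DEFAULT_GEOMETRY, rng=None) -> CgpGenome:
    """Draw a uniformly random valid genome.

    Every gene is sampled uniformly over its legal range, so feed-forward
    validity holds by construction.
    """
    rng = np.random.default_rng(rng)
    nodes = np.empty((geometry.n_nodes, 3), dtype=np.int64)
    for j in range(geometry.n_nodes):
        hi = geometry.max_source(j)
        nodes[j, 0] = rng.integers(0, len(geometry.functions))
        nodes[j, 1] = rng.integers(0, hi)
        nodes[j, 2] = rng.integers(0, hi)
    output_gene = int(rng.integers(0, geometry.n_inputs + geometry.n_nodes))
    return CgpGenome(nodes, output_gene, geometry)


def active_nodes(genome: CgpGenome) -> List[int]:
    """Node indices reachable from the output gene, in evaluation order.

    Traversal is arity-aware: ``abs`` reads only its first connection gene,
    so its second source does not activate anything.  The returned list is
    sorted ascending, which is a topological order because sources always
    lie in strictly earlier columns.
    """
    genome.validate()
    geo = genome.geometry
    needed = set()
    stack = [genome.output_gene - geo.n_inputs] if genome.output_gene >= geo.n_inputs else []
    while stack:
        j = stack.pop()
        if j in needed:
            continue
        needed.add(j)
        f, a, b = genome.nodes[j]
        sources = (a,) if FUNCTION_ARITY[geo.functions[f]] == 1 else (a, b)
        for s in sources:
            if s >= geo.n_inputs:
                stack.append(int(s) - geo.n_inputs)
    return sorted(needed)


def apply_function(function_id: int, a, b):
    """Apply one primitive to scalars or same-shape arrays; always finite.

    Division is protected: where |b| < 1e-6 the numerator is returned
    unchanged (total, deterministic, scale-preserving).  Outputs are clamped
    to +/-1e150 so that no chain of multiplications can reach infinity.
    """
    return _apply_name(FUNCTION_NAMES[function_id], a, b)


def _apply_name(name: str, a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if name == "add":
        out = a + b
    elif name == "sub":
        out = a - b
    elif name == "mul":
        out = a * b
    elif name == "div":
        safe = np.abs(b) >= DIV_EPS
        out = np.divide(a, b, out=a.copy(), where=safe)
    elif name == "mean":
        out = 0.5 * (a + b)
    elif name == "min":
        out = np.minimum(a, b)
    elif name == "max":
        out = np.maximum(a, b)
    elif name == "abs":
        out = np.abs(a)
    else:  # pragma: no cover
        raise ValueError(f"unknown function {name}")
    out = np.clip(out, -VALUE_CLAMP, VALUE_CLAMP)
    return out if out.ndim else float(out)


def evaluate_batch(genome: CgpGenome, inputs: np.ndarray) -> np.ndarray:
    """Evaluate the genome on a batch of input rows; returns shape (n,).

    Only active nodes are computed; by CGP neutrality this equals evaluating
    the full grid.  ``inputs`` has shape (n, n_inputs).
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    geo = genome.geometry
    if inputs.shape[1] != geo.n_inputs:
        raise ValueError(
            f"arity mismatch: {inputs.shape[1]} inputs, expected {geo.n_inputs}"
        )
    if not np.all(np.isfinite(inputs)):
        raise ValueError("arity mismatch: non-finite inputs")
    values: Dict[int, np.ndarray] = {}

    def source(s: int) -> np.ndarray:
        return inputs[:, s] if s < geo.n_inputs else values[s - geo.n_inputs]

    for j in active_nodes(genome):
        f, a, b = genome.nodes[j]
        name = geo.functions[int(f)]
        a_val = source(int(a))
        # arity-1 nodes never activate their second source
        b_val = a_val if FUNCTION_ARITY[name] == 1 else source(int(b))
        values[j] = _apply_name(name, a_val, b_val)
    return np.array(source(genome.output_gene), dtype=float, copy=True)


def evaluate(genome: CgpGenome, inputs: Sequence[float]) -> float:
    """Evaluate the decoded expression on one 32-vector of inputs."""
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 1:
        raise ValueError("arity mismatch: expected a flat input vector")
    return float(evaluate_batch(genome, inputs[None, :])[0])


def mutate(genome: CgpGenome, per_gene_rate: float = 0.02, rng=None) -> CgpGenome:
    """Point mutation: each gene independently resampled with given rate.

    Resampling is uniform over the gene's legal range (the old value may be
    redrawn).  The parent is left unmodified; the child is always valid.
    """
    if not 0.0 <= per_gene_rate <= 1.0:
        raise ValueError("per_gene_rate must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    geo = genome.geometry
    child = genome.copy()
    # one Bernoulli draw per gene, in a fixed order for reproducibility
    flags = rng.random((geo.n_nodes, 3)) < per_gene_rate
    for j in range(geo.n_nodes):
        hi = geo.max_source(j)
        if flags[j, 0]:
            child.nodes[j, 0] = rng.integers(0, len(geo.functions))
        if flags[j, 1]:
            child.nodes[j, 1] = rng.integers(0, hi)
        if flags[j, 2]:
            child.nodes[j, 2] = rng.integers(0, hi)
    if rng.random() < per_gene_rate:
        child.output_gene = int(rng.integers(0, geo.n_inputs + geo.n_nodes))
    return child


def crossover(parent_a: CgpGenome, parent_b: CgpGenome, rng=None) -> CgpGenome:
    """Uniform node-wise crossover: each node triple (and the output gene)
    is inherited wholly from one parent, chosen by fair coin.

    Because legal gene ranges depend only on node position, any mixture of
    two valid parents is valid.
    """
    if parent_a.geometry != parent_b.geometry:
        raise ValueError("incompatible parents: geometry mismatch")
    rng = np.random.default_rng(rng)
    take_a = rng.random(parent_a.geometry.n_nodes) < 0.5
    nodes = np.where(take_a[:, None], parent_a.nodes, parent_b.nodes)
    output = parent_a.output_gene if rng.random() < 0.5 else parent_b.output_gene
    return CgpGenome(nodes.copy(), output, parent_a.geometry)


# ---------------------------------------------------------------------------
# Serialisation: function names by name, not index, so files stay readable
# and stable if the set is ever reordered.


def genome_to_dict(genome: CgpGenome) -> dict:
    geo = genome.geometry
    return {
        "geometry": {
            "rows": geo.rows,
            "cols": geo.cols,
            "n_inputs": geo.n_inputs,
            "functions": list(geo.functions),
        },
        "nodes": [
            [geo.functions[int(f)], int(a), int(b)] for f, a, b in genome.nodes
        ],
        "output": int(genome.output_gene),
    }


def genome_from_dict(data: dict) -> CgpGenome:
    try:
        g = data["geometry"]
        geometry = CgpGeometry(
            rows=int(g["rows"]),
            cols=int(g["cols"]),
            n_inputs=int(g["n_inputs"]),
            functions=tuple(g["functions"]),
        )
        name_to_id = {name: i for i, name in enumerate(geometry.functions)}
        nodes = np.array(
            [[name_to_id[f], int(a), int(b)] for f, a, b in data["nodes"]],
            dtype=np.int64,
        )
        genome = CgpGenome(nodes, int(data["output"]), geometry)
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed genome: {exc}") from exc
    genome.validate()
    return genome
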