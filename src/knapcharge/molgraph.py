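"""Molecular graphs, SDF-dialect I/O, k-neighbourhoods and canonical environment keys.

A molecule is modelled as an undirected vertex-coloured graph ``G = (V, E, t)``:
vertices are atoms, edges are bonds, and ``t`` labels every atom with a type
drawn from an alphabet (chemical elements by default, or richer force-field
atom types).  Bond orders are read from input files but deliberately ignored:
the chemical-environment model colours vertices only.

Partial charges live on a 0.001 e fixed-point grid (the precision at which
reference repositories publish them); internally they are handled as integer
millicharges so rounding and scaling are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Atom",
    "MolecularGraph",
    "RootedEnvironment",
    "ParseError",
    "ValidationError",
    "charge_to_milli",
    "milli_to_charge",
    "read_molecules",
    "write_molecules",
    "write_charges",
    "k_neighbourhood",
    "induced_environment",
    "canonical_key",
]

CHARGE_TOL = 1e-9


class ParseError(ValueError):
    """Malformed molecule record; carries the record index and line number."""

    def __init__(self, message: str, record: int | None = None, line: int | None = None):
        loc = []
        if record is not None:
            loc.append(f"record {record}")
        if line is not None:
            loc.append(f"line {line}")
        super().__init__(f"{message} ({', '.join(loc)})" if loc else message)
        self.record = record
        self.line = line


class ValidationError(ValueError):
    """A molecule or charge list violates a structural invariant."""


def charge_to_milli(x: float) -> int:
    """Convert a charge in e to integer millicharge, requiring a 0.001 multiple."""
    m = x * 1000.0
    r = round(m)
    if abs(m - r) > CHARGE_TOL * 1000.0 + 1e-6:
        raise ValidationError(f"charge {x!r} is not a multiple of 0.001")
    return int(r)


def milli_to_charge(m: int) -> float:
    return m / 1000.0


@dataclass(frozen=True)
class Atom:
    """One atom: a type label and an optional partial charge (e, 3 decimals)."""

    type_label: str
    charge: float | None = None


@dataclass
class MolecularGraph:
    """A connected molecular graph with optional per-atom partial charges.

    Atom indices are 1-based, matching SDF conventions; ``bonds`` holds
    unordered index pairs.  ``total_charge`` is the molecule's target total
    charge in elementary-charge units.
    """

    atoms: list[Atom]
    bonds: set[tuple[int, int]]
    total_charge: float | None = None
    identifier: str = ""
    _adj: dict[int, list[int]] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise ValidationError("molecule has no atoms")
        norm: set[tuple[int, int]] = set()
        for b in self.bonds:
            i, j = b
            if not (1 <= i <= n and 1 <= j <= n):
                raise ValidationError(f"bond {b} references an invalid atom index (n={n})")
            if i == j:
                raise ValidationError(f"self-loop bond on atom {i}")
            norm.add((min(i, j), max(i, j)))
        if len(norm) != len(self.bonds):
            raise ValidationError("duplicate bonds")
        self.bonds = norm
        for idx, a in enumerate(self.atoms, start=1):
            if a.charge is not None:
                try:
                    charge_to_milli(a.charge)
                except ValidationError:
                    raise ValidationError(
                        f"atom {idx} charge {a.charge!r} is not a multiple of 0.001"
                    ) from None
        if not self._connected():
            raise ValidationError(f"molecule {self.identifier!r} is not connected")

    # -- basic accessors -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def has_charges(self) -> bool:
        return all(a.charge is not None for a in self.atoms)

    def charges(self) -> list[float]:
        if not self.has_charges:
            raise ValidationError(f"molecule {self.identifier!r} is missing charges")
        return [a.charge for a in self.atoms]  # type: ignore[misc]

    def adjacency(self) -> dict[int, list[int]]:
        if self._adj is None:
            adj: dict[int, list[int]] = {i: [] for i in range(1, self.n_atoms + 1)}
            for i, j in sorted(self.bonds):
                adj[i].append(j)
                adj[j].append(i)
            self._adj = adj
        return self._adj

    def _connected(self) -> bool:
        adj: dict[int, list[int]] = {i: [] for i in range(1, len(self.atoms) + 1)}
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        seen = {1}
        stack = [1]
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == len(self.atoms)

    # -- transforms ------------------------------------------------------

    def with_charges(self, charges: Sequence[float], total_charge: float | None = None) -> "MolecularGraph":
        if len(charges) != self.n_atoms:
            raise ValidationError(
                f"expected {self.n_atoms} charges, got {len(charges)}"
            )
        atoms = [Atom(a.type_label, round(c, 3)) for a, c in zip(self.atoms, charges)]
        return MolecularGraph(atoms, set(self.bonds), total_charge if total_charge is not None else self.total_charge, self.identifier)

    def permuted(self, perm: Sequence[int]) -> "MolecularGraph":
        """Return the graph with atoms reordered; ``perm[new-1] = old`` (1-based)."""
        if sorted(perm) != list(range(1, self.n_atoms + 1)):
            raise ValidationError("perm must be a permutation of 1..n")
        old_to_new = {old: new for new, old in enumerate(perm, start=1)}
        atoms = [self.atoms[old - 1] for old in perm]
        bonds = {(old_to_new[i], old_to_new[j]) for i, j in self.bonds}
        return MolecularGraph(atoms, bonds, self.total_charge, self.identifier)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i, a in enumerate(self.atoms, start=1):
            g.add_node(i, type_label=a.type_label, charge=a.charge)
        g.add_edges_from(self.bonds)
        return g


@dataclass
class RootedEnvironment:
    """The induced subgraph of a k-neighbourhood, rooted at its central atom.

    ``root_index`` refers to the environment's own (re-indexed) atoms;
    ``source_indices[i-1]`` maps environment atom i back to the parent
    molecule's atom index.
    """

    graph: MolecularGraph
    root_index: int
    shell: int
    source_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.shell < 0:
            raise ValidationError("shell must be >= 0")
        reach = k_neighbourhood(self.graph, self.root_index, self.shell)
        if reach != set(range(1, self.graph.n_atoms + 1)):
            raise ValidationError(
                "environment contains atoms beyond the shell radius from the root"
            )


# -- neighbourhoods ------------------------------------------------------


def k_neighbourhood(molecule: MolecularGraph, v: int, k: int) -> set[int]:
    """All atoms with a path of length <= k to v (the k-neighbourhood N_k(v)).

    Follows the recursion N_0(v) = {v},
    N_k(v) = N_{k-1}(v) ∪ ⋃_{u ∈ N_{k-1}(v)} N(u),
    which equals the breadth-first ball of radius k around v.
    """
    if not (1 <= v <= molecule.n_atoms):
        raise ValidationError(f"atom index {v} out of range 1..{molecule.n_atoms}")
    if k < 0:
        raise ValidationError("k must be >= 0")
    adj = molecule.adjacency()
    current = {v}
    frontier = {v}
    for _ in range(k):
        nxt = set()
        for u in frontier:
            for w in adj[u]:
                if w not in current:
                    nxt.add(w)
        if not nxt:
            break
        current |= nxt
        frontier = nxt
    return current


def induced_environment(molecule: MolecularGraph, v: int, k: int) -> RootedEnvironment:
    """Induced subgraph on N_k(v), re-indexed 1..|N_k(v)| in original atom order."""
    members = sorted(k_neighbourhood(molecule, v, k))
    old_to_new = {old: new for new, old in enumerate(members, start=1)}
    atoms = [molecule.atoms[old - 1] for old in members]
    member_set = set(members)
    bonds = {
        (old_to_new[i], old_to_new[j])
        for i, j in molecule.bonds
        if i in member_set and j in member_set
    }
    sub = MolecularGraph(atoms, bonds, None, molecule.identifier)
    return RootedEnvironment(sub, old_to_new[v], k, source_indices=members)


# -- canonical keys for rooted environments ------------------------------
#
# Two environments must receive the same key iff a type-preserving graph
# isomorphism mapping root to root exists.  We canonicalise with iterative
# colour refinement seeded by (distance from root, atom type), followed by
# individualisation of the smallest non-singleton colour class when
# refinement alone does not yield a discrete partition.  The key encodes the
# canonically relabelled graph itself, so key equality implies isomorphism by
# construction.


def _refine(n: int, adj: list[list[int]], colors: list[int]) -> list[int]:
    while True:
        sigs = [
            (colors[u], tuple(sorted(colors[w] for w in adj[u])))
            for u in range(n)
        ]
        order = {s: i for i, s in enumerate(sorted(set(sigs)))}
        new = [order[s] for s in sigs]
        if new == colors:
            return colors
        colors = new


def _canonical_string(n: int, adj: list[list[int]], types: list[str], root: int,
                      colors: list[int]) -> str:
    colors = _refine(n, adj, colors)
    # locate smallest non-singleton colour class
    by_color: dict[int, list[int]] = {}
    for u, c in enumerate(colors):
        by_color.setdefault(c, []).append(u)
    target = None
    for c in sorted(by_color):
        if len(by_color[c]) > 1:
            target = by_color[c]
            break
    if target is None:
        # discrete partition: colours give the canonical order
        perm = sorted(range(n), key=lambda u: colors[u])
        pos = [0] * n
        for p, u in enumerate(perm):
            pos[u] = p
        edges = sorted(
            (min(pos[u], pos[w]), max(pos[u], pos[w]))
            for u in range(n)
            for w in adj[u]
            if u < w
        )
        return json.dumps(
            [n, pos[root], [types[u] for u in perm], edges],
            separators=(",", ":"),
        )
    best: str | None = None
    fresh = max(colors) + 1
    for u in target:
        branched = list(colors)
        branched[u] = fresh
        cand = _canonical_string(n, adj, types, root, branched)
        if best is None or cand < best:
            best = cand
    return best  # type: ignore[return-value]


def canonical_key(env: RootedEnvironment) -> str:
    """Deterministic canonical key of a rooted, vertex-typed environment.

    Key equality between two environments holds iff they are isomorphic via a
    type-preserving map sending root to root.
    """
    g = env.graph
    n = g.n_atoms
    adj0 = g.adjacency()
    adj = [[w - 1 for w in adj0[u + 1]] for u in range(n)]
    types = [a.type_label for a in g.atoms]
    root = env.root_index - 1
    # distances from root (root is the unique distance-0 vertex)
    dist = [-1] * n
    dist[root] = 0
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if dist[w] < 0:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    init = [(dist[u], types[u]) for u in range(n)]
    order = {s: i for i, s in enumerate(sorted(set(init)))}
    colors = [order[s] for s in init]
    return _canonical_string(n, adj, types, root, colors)


# -- SDF-dialect and JSON I/O --------------------------------------------
#
# V2000 connection table, one molecule per record, with data fields
#   > <PARTIAL_CHARGES>  one decimal per atom, file order, 3 decimals
#   > <TOTAL_CHARGE>     a single decimal
#   > <ATOM_TYPES>       optional, one token per atom, overriding the element
#                        symbol column as the type label


def _parse_sdf_record(lines: list[str], first_line: int, record_idx: int) -> MolecularGraph:
    if len(lines) < 4:
        raise ParseError("record too short for a V2000 header", record_idx, first_line)
    name = lines[0].strip()
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise ParseError("malformed counts line", record_idx, first_line + 3) from None
    if n_atoms < 1:
        raise ParseError("record declares no atoms", record_idx, first_line + 3)
    atom_start = 4
    bond_start = atom_start + n_atoms
    if len(lines) < bond_start + n_bonds:
        raise ParseError("truncated atom/bond block", record_idx, first_line + len(lines) - 1)
    symbols: list[str] = []
    for i in range(n_atoms):
        ln = lines[atom_start + i]
        if len(ln) >= 34:
            sym = ln[31:34].strip()
        else:
            parts = ln.split()
            sym = parts[3] if len(parts) > 3 else ""
        if not sym:
            raise ParseError("missing atom symbol", record_idx, first_line + atom_start + i)
        symbols.append(sym)
    bonds: set[tuple[int, int]] = set()
    for i in range(n_bonds):
        ln = lines[bond_start + i]
        try:
            a = int(ln[0:3])
            b = int(ln[3:6])
        except (ValueError, IndexError):
            raise ParseError("malformed bond line", record_idx, first_line + bond_start + i) from None
        bonds.add((min(a, b), max(a, b)))
    # data fields
    fields: dict[str, list[str]] = {}
    i = bond_start + n_bonds
    while i < len(lines) and not lines[i].startswith("M  END"):
        i += 1
    i += 1
    while i < len(lines):
        ln = lines[i]
        if ln.startswith(">"):
            lo = ln.find("<")
            hi = ln.find(">", lo)
            if lo < 0 or hi < 0:
                raise ParseError("malformed data header", record_idx, first_line + i)
            fname = ln[lo + 1 : hi]
            i += 1
            body: list[str] = []
            while i < len(lines) and lines[i].strip() != "":
                body.append(lines[i].strip())
                i += 1
            fields[fname] = body
        else:
            i += 1

    charges: list[float] | None = None
    if "PARTIAL_CHARGES" in fields:
        vals = [tok for ln in fields["PARTIAL_CHARGES"] for tok in ln.split()]
        if len(vals) != n_atoms:
            raise ParseError(
                f"PARTIAL_CHARGES has {len(vals)} values for {n_atoms} atoms",
                record_idx,
                first_line,
            )
        try:
            charges = [float(v) for v in vals]
        except ValueError:
            raise ParseError("non-numeric partial charge", record_idx, first_line) from None
    total: float | None = None
    if "TOTAL_CHARGE" in fields:
        toks = [tok for ln in fields["TOTAL_CHARGE"] for tok in ln.split()]
        if len(toks) != 1:
            raise ParseError("TOTAL_CHARGE must hold a single value", record_idx, first_line)
        total = float(toks[0])
    labels = symbols
    if "ATOM_TYPES" in fields:
        toks = [tok for ln in fields["ATOM_TYPES"] for tok in ln.split()]
        if len(toks) != n_atoms:
            raise ParseError(
                f"ATOM_TYPES has {len(toks)} tokens for {n_atoms} atoms",
                record_idx,
                first_line,
            )
        labels = toks
    if total is None:
        if charges is None:
            raise ValidationError(
                f"record {record_idx}: neither TOTAL_CHARGE nor PARTIAL_CHARGES present"
            )
        total = round(sum(charges))
    atoms = [
        Atom(lbl, round(c, 3) if charges is not None else None)
        for lbl, c in zip(labels, charges if charges is not None else [None] * n_atoms)  # type: ignore[list-item]
    ]
    try:
        return MolecularGraph(atoms, bonds, float(total), name or f"record_{record_idx}")
    except ValidationError as e:
        raise ParseError(str(e), record_idx, first_line) from None


def _read_sdf(path: Path) -> list[MolecularGraph]:
    text = path.read_text()
    out: list[MolecularGraph] = []
    record: list[str] = []
    first_line = 1
    record_idx = 1
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if raw.strip() == "$$$$":
            if any(l.strip() for l in record):
                out.append(_parse_sdf_record(record, first_line, record_idx))
                record_idx += 1
            record = []
            first_line = lineno + 1
        else:
            record.append(raw)
    if any(l.strip() for l in record):
        out.append(_parse_sdf_record(record, first_line, record_idx))
    return out


def _mol_from_json_obj(obj: dict, record_idx: int) -> MolecularGraph:
    try:
        atoms = [Atom(a["type"], a.get("charge")) for a in obj["atoms"]]
        bonds = {(int(i), int(j)) for i, j in obj["bonds"]}
        total = obj.get("total_charge")
        if total is None:
            if any(a.charge is None for a in atoms):
                raise ValidationError(
                    f"record {record_idx}: neither total_charge nor full charges present"
                )
            total = round(sum(a.charge for a in atoms))  # type: ignore[misc]
        return MolecularGraph(atoms, bonds, float(total), obj.get("identifier", f"record_{record_idx}"))
    except (KeyError, TypeError) as e:
        raise ParseError(f"malformed JSON molecule: {e}", record_idx) from None


def read_molecules(path: str | Path, format: str | None = None) -> list[MolecularGraph]:
    """Read molecules from an SDF-dialect or JSON file, preserving atom order."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sdf"
    if format == "sdf":
        return _read_sdf(path)
    if format == "json":
        data = json.loads(path.read_text() or "[]")
        if isinstance(data, dict):
            data = [data]
        return [_mol_from_json_obj(obj, i) for i, obj in enumerate(data, start=1)]
    raise ValueError(f"unknown format {format!r}")


def _format_sdf_record(mol: MolecularGraph) -> str:
    lines = [mol.identifier, "  knapcharge", ""]
    lines.append(f"{mol.n_atoms:>3d}{len(mol.bonds):>3d}  0  0  0  0  0  0  0  0999 V2000")
    plain = all(
        0 < len(a.type_label) <= 3 and not any(ch.isspace() for ch in a.type_label)
        for a in mol.atoms
    )
    for a in mol.atoms:
        sym = a.type_label if plain else "X"
        lines.append(f"    0.0000    0.0000    0.0000 {sym:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j in sorted(mol.bonds):
        lines.append(f"{i:>3d}{j:>3d}  1  0")
    lines.append("M  END")
    if mol.has_charges:
        lines.append("> <PARTIAL_CHARGES>")
        lines.extend(f"{a.charge:.3f}" for a in mol.atoms)
        lines.append("")
    if mol.total_charge is not None:
        lines.append("> <TOTAL_CHARGE>")
        lines.append(f"{mol.total_charge:.3f}")
        lines.append("")
    if not plain:
        lines.append("> <ATOM_TYPES>")
        lines.append(" ".join(a.type_label for a in mol.atoms))
        lines.append("")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


def write_molecules(molecules: Iterable[MolecularGraph], path: str | Path) -> None:
    """Write molecules to the SDF dialect (charges/total emitted when present)."""
    Path(path).write_text("".join(_format_sdf_record(m) for m in molecules))


def write_charges(molecule: MolecularGraph, charges: Sequence[float], path: str | Path) -> None:
    """Write ``molecule`` with the given per-atom charges to the SDF dialect.

    Charges must be 0.001-multiples, one per atom; reading the output back
    recovers atoms, bonds and charges exactly.
    """
    if len(charges) != molecule.n_atoms:
        raise ValidationError(
            f"expected {molecule.n_atoms} charges, got {len(charges)}"
        )
    for c in charges:
        charge_to_milli(c)
    total = molecule.total_charge
    if total is None:
        total = round(sum(charges), 3)
    write_molecules([molecule.with_charges(list(charges), total)], path)
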