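"""Independent oracles and random fixture builders for the test suite.

Everything here is deliberately naive: brute force, enumeration, and
direct recursion, kept separate from the package's optimized paths so
the two can disagree.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from organflux.gpr import AND, EMPTY, GENE, OR, GPRTree
from organflux.model import MetabolicModel, Metabolite, Reaction

# --------------------------------------------------------------------------
# GPR oracles
# --------------------------------------------------------------------------


def oracle_knockout(tree: GPRTree, deleted: set) -> bool:
    """Direct truth-table recursion over the boolean rule."""
    if tree.kind == EMPTY:
        return True
    if tree.kind == GENE:
        return tree.gene not in deleted
    vals = [oracle_knockout(c, deleted) for c in tree.children]
    return all(vals) if tree.kind == AND else any(vals)


def oracle_expression(tree: GPRTree, values: dict):
    """min/max recursion skipping data-free subtrees."""
    if tree.kind == EMPTY:
        return None
    if tree.kind == GENE:
        return values.get(tree.gene)
    sub = [oracle_expression(c, values) for c in tree.children]
    sub = [v for v in sub if v is not None]
    if not sub:
        return None
    return min(sub) if tree.kind == AND else max(sub)


def oracle_limiting(tree: GPRTree, values: dict) -> set:
    """Enumerate root-to-leaf paths; keep leaves on fully selecting paths."""

    def paths(node, acc):
        if node.kind == GENE:
            yield acc + [node]
        else:
            for child in node.children:
                yield from paths(child, acc + [node])

    total = oracle_expression(tree, values)
    out = set()
    for path in paths(tree, []):
        leaf = path[-1]
        if leaf.gene not in values or values[leaf.gene] != total:
            continue
        # every edge on the path must be value-selecting
        ok = True
        for parent, child in zip(path, path[1:]):
            pv = oracle_expression(parent, values)
            cv = oracle_expression(child, values)
            if cv is None or cv != pv:
                ok = False
                break
        if ok:
            out.add(leaf.gene)
    return out


def random_tree(rng: np.random.Generator, genes: list, max_depth: int = 4) -> GPRTree:
    if max_depth == 0 or rng.random() < 0.4:
        return GPRTree(GENE, gene=str(rng.choice(genes)))
    kind = AND if rng.random() < 0.5 else OR
    n = int(rng.integers(2, 4))
    return GPRTree(
        kind, children=tuple(random_tree(rng, genes, max_depth - 1) for _ in range(n))
    )


# --------------------------------------------------------------------------
# LP vertex-enumeration oracle
# --------------------------------------------------------------------------


def oracle_max_flux(model: MetabolicModel, objective_id: str, tol: float = 1e-9):
    """Brute-force LP maximum by enumerating basic feasible points.

    For max c.v s.t. S v = 0, lb <= v <= ub, every vertex of the
    feasible polytope fixes enough variables at a bound that the
    remaining square system (through S) is determined. We enumerate
    all subsets of variables fixed at lower/upper bounds, solve the
    least-squares system for the free ones, and keep feasible points.
    Exponential, fine for <= 8 reactions.
    """
    S = model.stoichiometric_matrix().toarray()
    lb, ub = model.bounds_arrays()
    n = S.shape[1]
    j_obj = model.reaction_ids().index(objective_id)
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_free = rank  # free variables solved through S
    best = None

    for free in combinations(range(n), n_free):
        fixed = [j for j in range(n) if j not in free]
        for choice in product((0, 1), repeat=len(fixed)):
            v = np.zeros(n)
            for j, pick in zip(fixed, choice):
                v[j] = lb[j] if pick == 0 else ub[j]
            if n_free:
                A = S[:, list(free)]
                b = -S[:, fixed] @ v[fixed] if fixed else np.zeros(S.shape[0])
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[list(free)] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            val = v[j_obj]
            if best is None or val > best:
                best = val
    return best


def random_toy_lp(rng: np.random.Generator, max_reactions: int = 8) -> tuple[MetabolicModel, str]:
    """Small random network with an exchange inlet, internal web and demand outlet."""
    n_mets = int(rng.integers(2, 5))
    model = MetabolicModel(id="rand", compartments={"c"})
    for i in range(n_mets):
        model.add_metabolite(Metabolite(id=f"m{i}", compartment="c"))
    model.add_boundary_reaction("m0", "exchange", -float(rng.integers(1, 20)), 0.0)
    n_internal = int(rng.integers(1, max_reactions - 1))
    for k in range(n_internal):
        i, j = rng.choice(n_mets, size=2, replace=False)
        rev = rng.random() < 0.3
        cap = float(rng.integers(1, 15))
        model.add_reaction(
            Reaction(
                f"r{k}",
                {f"m{i}": -1.0, f"m{j}": 1.0},
                -cap if rev else 0.0,
                cap,
            )
        )
    target = f"m{rng.integers(0, n_mets)}"
    obj = model.add_boundary_reaction(target, "demand", 0.0, float(rng.integers(1, 25)))
    return model, obj.id


# --------------------------------------------------------------------------
# hand-built fixtures
# --------------------------------------------------------------------------


def chain_model(caps=(10.0, 1000.0, 1000.0, 1000.0)) -> MetabolicModel:
    """EX_A (uptake cap) -> T_A -> R1 -> DM_B linear chain."""
    m = MetabolicModel(id="chain", compartments={"e", "c"})
    m.add_metabolite(Metabolite(id="a_e", compartment="e"))
    m.add_metabolite(Metabolite(id="a_c", compartment="c"))
    m.add_metabolite(Metabolite(id="b_c", compartment="c"))
    m.add_boundary_reaction("a_e", "exchange", -caps[0], 0.0)
    m.add_reaction(Reaction("T_A", {"a_e": -1, "a_c": 1}, 0.0, caps[1], kind="transport"))
    m.add_reaction(Reaction("R1", {"a_c": -1, "b_c": 1}, 0.0, caps[2]))
    m.add_boundary_reaction("b_c", "demand", 0.0, caps[3])
    return m


def parallel_model(cap1=10.0, cap2=10.0, inlet=30.0, outlet=1000.0) -> MetabolicModel:
    """Two parallel routes from A to B feeding one demand."""
    m = MetabolicModel(id="parallel", compartments={"c"})
    for mid in ("a", "x", "y", "b"):
        m.add_metabolite(Metabolite(id=mid, compartment="c"))
    m.add_boundary_reaction("a", "exchange", -inlet, 0.0)
    m.add_reaction(Reaction("P1a", {"a": -1, "x": 1}, 0.0, cap1))
    m.add_reaction(Reaction("P1b", {"x": -1, "b": 1}, 0.0, 1000.0))
    m.add_reaction(Reaction("P2a", {"a": -1, "y": 1}, 0.0, cap2))
    m.add_reaction(Reaction("P2b", {"y": -1, "b": 1}, 0.0, 1000.0))
    m.add_boundary_reaction("b", "demand", 0.0, outlet)
    return m
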