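"""Reaction networks: representation, parsing, and structural predicates.

A network is an ordered list of species together with an ordered list of
reactions, each reaction an ordered pair of complexes (source -> target).
The source matrix ``Gamma_l`` holds the source stoichiometries and the
stoichiometric matrix ``Gamma`` holds the reaction vectors
(target - source), one column per reaction.

Everything here is decided in exact rational arithmetic: rank, kernel
vectors, positive dependence of the reaction vectors (dynamical
nontriviality), collinearity of sources, and canonical forms.  Floating
point enters only in the dynamics/stability modules.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from . import _exact
from ._exact import sign


class NetworkError(ValueError):
    """Malformed network input (parse error, invalid reaction, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComplexVec:
    """A chemical complex as a stoichiometry vector over ordered species."""

    coeffs: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.coeffs):
            raise NetworkError(f"negative stoichiometric coefficient in {self.coeffs}")

    @property
    def molecularity(self) -> int:
        return sum(self.coeffs)

    def format(self, species: Sequence[str]) -> str:
        terms = []
        for c, s in zip(self.coeffs, species):
            if c == 0:
                continue
            terms.append(s if c == 1 else f"{c}{s}")
        return " + ".join(terms) if terms else "0"


@dataclass(frozen=True)
class Reaction:
    """An ordered pair of complexes; the reaction vector is target - source."""

    source: ComplexVec
    target: ComplexVec
    label: str | None = None

    def __post_init__(self) -> None:
        if self.source.coeffs == self.target.coeffs:
            raise NetworkError("reaction with source == target is not allowed")
        if len(self.source.coeffs) != len(self.target.coeffs):
            raise NetworkError("source and target have different species counts")

    @property
    def vector(self) -> tuple[int, ...]:
        return tuple(t - s for s, t in zip(self.source.coeffs, self.target.coeffs))


@dataclass(frozen=True)
class Network:
    """Ordered species plus ordered reactions."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        for r in self.reactions:
            if len(r.source.coeffs) != len(self.species):
                raise NetworkError("reaction dimension does not match species count")
        for i, s in enumerate(self.species):
            if all(
                r.source.coeffs[i] == 0 and r.target.coeffs[i] == 0
                for r in self.reactions
            ):
                raise NetworkError(f"species {s!r} appears in no complex")

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def m(self) -> int:
        return len(self.reactions)

    @property
    def gamma(self) -> np.ndarray:
        """Stoichiometric matrix, n x m, integer."""
        return np.array([r.vector for r in self.reactions], dtype=np.int64).T

    @property
    def gamma_l(self) -> np.ndarray:
        """Source matrix, n x m, nonnegative integer."""
        return np.array([r.source.coeffs for r in self.reactions], dtype=np.int64).T

    @property
    def target_matrix(self) -> np.ndarray:
        return np.array([r.target.coeffs for r in self.reactions], dtype=np.int64).T

    def to_text(self) -> str:
        lines = []
        for r in self.reactions:
            line = f"{r.source.format(self.species)} -> {r.target.format(self.species)}"
            if r.label:
                line += f" @ {r.label}"
            lines.append(line)
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "species": list(self.species),
            "reactions": [
                {
                    "source": {
                        s: c for s, c in zip(self.species, r.source.coeffs) if c
                    },
                    "target": {
                        s: c for s, c in zip(self.species, r.target.coeffs) if c
                    },
                    **({"label": r.label} if r.label else {}),
                }
                for r in self.reactions
            ],
        }
        return json.dumps(payload, indent=2)

    def embedded_graph(self) -> tuple[list[tuple[int, ...]], list[tuple[int, int]]]:
        """Euclidean embedded graph: complexes as lattice points, reactions as arcs.

        Returns (nodes, edges) with edges as index pairs into nodes.
        """
        nodes: list[tuple[int, ...]] = []
        index: dict[tuple[int, ...], int] = {}
        edges = []
        for r in self.reactions:
            pair = []
            for cx in (r.source.coeffs, r.target.coeffs):
                if cx not in index:
                    index[cx] = len(nodes)
                    nodes.append(cx)
                pair.append(index[cx])
            edges.append(tuple(pair))
        return nodes, edges

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_text()


@dataclass(frozen=True)
class NontrivialityCertificate:
    """Witnessed decision of ker Gamma ∩ R+^m != {} (Stiemke alternative).

    Exactly one of the witnesses is set: a strictly positive rational kernel
    vector when the network is dynamically nontrivial, or a separating
    vector v with Gamma^T v >= 0, != 0 when it is trivial.  Both verify by
    direct multiplication.
    """

    status: bool
    positive_kernel_vector: tuple[Fraction, ...] | None = None
    separating_vector: tuple[Fraction, ...] | None = None

    def __bool__(self) -> bool:
        return self.status


# ---------------------------------------------------------------------------
# parsing / construction
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(\d+)?\s*([A-Za-z_][A-Za-z0-9_]*)$")


def _parse_complex(text: str, species_order: list[str]) -> dict[str, int]:
    text = text.strip()
    if text == "0":
        return {}
    coeffs: dict[str, int] = {}
    for term in text.split("+"):
        m = _TERM_RE.match(term.strip())
        if not m:
            raise NetworkError(f"malformed complex term {term.strip()!r}")
        k = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        if k <= 0:
            raise NetworkError(f"nonpositive coefficient in term {term.strip()!r}")
        coeffs[name] = coeffs.get(name, 0) + k
        if name not in species_order:
            species_order.append(name)
    return coeffs


def parse_network(text: str) -> Network:
    """Parse a plain-text reaction list, one reaction per line.

    Lines look like ``2X -> 3X + Y @ k1`` (the rate label is optional);
    complexes are ``0`` or '+'-separated terms ``kS``.  Species are ordered
    by first appearance and reactions keep input order.
    """
    species_order: list[str] = []
    raw: list[tuple[dict[str, int], dict[str, int], str | None]] = []
    for lineno, line in enumerate(text.strip().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label = None
        if "@" in line:
            line, label = (part.strip() for part in line.split("@", 1))
        if "->" not in line:
            raise NetworkError(f"line {lineno}: missing '->'")
        lhs, rhs = line.split("->", 1)
        src = _parse_complex(lhs, species_order)
        tgt = _parse_complex(rhs, species_order)
        if src == tgt:
            raise NetworkError(f"line {lineno}: source equals target")
        raw.append((src, tgt, label))
    if not raw:
        raise NetworkError("empty network")
    species = tuple(species_order)
    reactions = tuple(
        Reaction(
            ComplexVec(tuple(src.get(s, 0) for s in species)),
            ComplexVec(tuple(tgt.get(s, 0) for s in species)),
            label,
        )
        for src, tgt, label in raw
    )
    return Network(species, reactions)


def network_from_arrays(
    sources: Iterable[Sequence[int]],
    targets: Iterable[Sequence[int]],
    species: Sequence[str] | None = None,
) -> Network:
    """Build a network from per-reaction source/target coefficient rows."""
    sources = [tuple(int(v) for v in s) for s in sources]
    targets = [tuple(int(v) for v in t) for t in targets]
    n = len(sources[0])
    if species is None:
        species = tuple(_default_species(n))
    reactions = tuple(
        Reaction(ComplexVec(s), ComplexVec(t)) for s, t in zip(sources, targets)
    )
    return Network(tuple(species), reactions)


def _default_species(n: int) -> list[str]:
    base = ["X", "Y", "Z", "W", "V", "U"]
    if n <= len(base):
        return base[:n]
    return [f"X{i+1}" for i in range(n)]


# ---------------------------------------------------------------------------
# structural predicates
# ---------------------------------------------------------------------------


def matrices(net: Network) -> tuple[np.ndarray, np.ndarray]:
    """Return (Gamma_l, Gamma)."""
    return net.gamma_l, net.gamma


def network_rank(net: Network) -> int:
    """Rank of the stoichiometric matrix over the rationals."""
    return _exact.rank([r.vector for r in net.reactions])


def molecularity_profile(net: Network) -> tuple[int, int]:
    """(max source molecularity, max target molecularity)."""
    return (
        max(r.source.molecularity for r in net.reactions),
        max(r.target.molecularity for r in net.reactions),
    )


def is_quadratic(net: Network) -> bool:
    """All source complexes at most bimolecular."""
    return molecularity_profile(net)[0] <= 2


def is_bimolecular(net: Network) -> bool:
    return max(molecularity_profile(net)) <= 2


def is_trimolecular(net: Network) -> bool:
    return max(molecularity_profile(net)) <= 3


def trivial_species(net: Network) -> set[int]:
    """Indices of species whose Gamma row is identically zero."""
    gamma = net.gamma
    return {i for i in range(net.n) if not gamma[i].any()}


def strip_trivial_species(net: Network) -> tuple[Network, tuple[str, ...]]:
    """Remove trivial species; returns (reduced network, removed names)."""
    triv = trivial_species(net)
    if not triv:
        return net, ()
    keep = [i for i in range(net.n) if i not in triv]
    removed = tuple(net.species[i] for i in sorted(triv))
    species = tuple(net.species[i] for i in keep)
    reactions = tuple(
        Reaction(
            ComplexVec(tuple(r.source.coeffs[i] for i in keep)),
            ComplexVec(tuple(r.target.coeffs[i] for i in keep)),
            r.label,
        )
        for r in net.reactions
    )
    return Network(species, reactions), removed


def is_dynamically_nontrivial(net: Network) -> NontrivialityCertificate:
    """Decide ker Gamma ∩ R+^m != {} with an exact rational witness.

    By Stiemke's alternative either a strictly positive kernel vector of
    Gamma exists (reaction vectors positively dependent) or there is v with
    Gamma^T v >= 0, != 0 (a linear function increasing along all orbits).
    """
    cols = [list(r.vector) for r in net.reactions]  # m rows of Gamma^T
    gamma_rows = [list(row) for row in zip(*cols)]  # n rows of Gamma
    kernel = _exact.nullspace(gamma_rows)
    if not kernel:
        # Gamma has full column rank: im Gamma^T = R^m, take Gamma^T v = 1
        v = _exact.solve(cols, [Fraction(1)] * net.m)
        assert v is not None
        return NontrivialityCertificate(False, separating_vector=tuple(v))
    if len(kernel) == 1:
        u = kernel[0]
        s = {sign(x) for x in u}
        if s == {1} or s == {-1}:
            if next(iter(s)) == -1:
                u = [-x for x in u]
            return NontrivialityCertificate(True, positive_kernel_vector=tuple(u))
        return NontrivialityCertificate(
            False, separating_vector=_separating_vector(cols, [u])
        )
    # kernel dimension >= 2: search for a positive combination by exact
    # vertex-style sweep; m is tiny so an LP relaxation with exact
    # verification is used.
    found = _positive_in_span(kernel)
    if found is not None:
        return NontrivialityCertificate(True, positive_kernel_vector=tuple(found))
    return NontrivialityCertificate(
        False, separating_vector=_separating_vector(cols, kernel)
    )


def _positive_in_span(kernel: list[list[Fraction]]) -> list[Fraction] | None:
    """A strictly positive vector in span(kernel), or None, exactly.

    Solved as an LP (maximise the minimum entry subject to sum = 1) with
    scipy, then rationalised and verified by exact arithmetic.
    """
    from scipy.optimize import linprog

    m = len(kernel[0])
    k = len(kernel)
    kmat = np.array([[float(x) for x in vec] for vec in kernel]).T  # m x k
    # variables: lambda (k), t;  maximise t  s.t.  K lambda - t >= 0, sum(K lambda)=1
    a_ub = np.hstack([-kmat, np.ones((m, 1))])
    a_eq = np.hstack([kmat.sum(axis=0, keepdims=True), np.zeros((1, 1))])
    res = linprog(
        c=np.concatenate([np.zeros(k), [-1.0]]),
        A_ub=a_ub,
        b_ub=np.zeros(m),
        A_eq=a_eq,
        b_eq=[1.0],
        bounds=[(None, None)] * (k + 1),
        method="highs",
    )
    if not res.success or res.x[-1] <= 1e-9:
        return None
    lam = [Fraction(x).limit_denominator(10**6) for x in res.x[:k]]
    u = [sum(l * vec[j] for l, vec in zip(lam, kernel)) for j in range(m)]
    if all(x > 0 for x in u):
        return u
    # nudge towards the analytic centre and retry with coarser denominators
    for denom in (10, 100, 1000):
        lam = [Fraction(x).limit_denominator(denom) for x in res.x[:k]]
        u = [sum(l * vec[j] for l, vec in zip(lam, kernel)) for j in range(m)]
        if all(x > 0 for x in u):
            return u
    return None


def _separating_vector(
    gamma_t_rows: list[list[int]], kernel: list[list[Fraction]]
) -> tuple[Fraction, ...]:
    """Exact v with Gamma^T v >= 0, != 0, given no positive kernel vector.

    Needs w >= 0, w != 0 orthogonal to ker Gamma (then w ∈ im Gamma^T and we
    solve Gamma^T v = w).  For a one-dimensional kernel spanned by a
    mixed-sign or zero-entry u the witness w is written down directly; for
    higher kernel dimension an LP + rationalisation is used.
    """
    m = len(gamma_t_rows)
    w: list[Fraction] | None = None
    if len(kernel) == 1:
        u = kernel[0]
        zero = [j for j, x in enumerate(u) if x == 0]
        if zero:
            w = [Fraction(0)] * m
            w[zero[0]] = Fraction(1)
        else:
            i = next(j for j, x in enumerate(u) if x > 0)
            j = next(j for j, x in enumerate(u) if x < 0)
            w = [Fraction(0)] * m
            w[i], w[j] = -u[j], u[i]  # w.u = -u_j u_i + u_i u_j = 0
    else:
        from scipy.optimize import linprog

        kmat = np.array([[float(x) for x in vec] for vec in kernel])  # k x m
        res = linprog(
            c=np.zeros(m),
            A_eq=np.vstack([kmat, np.ones((1, m))]),
            b_eq=np.concatenate([np.zeros(len(kernel)), [1.0]]),
            bounds=[(0, None)] * m,
            method="highs",
        )
        if res.success:
            for denom in (10**6, 1000, 100, 10):
                cand = [Fraction(x).limit_denominator(denom) for x in res.x]
                if (
                    all(x >= 0 for x in cand)
                    and any(x > 0 for x in cand)
                    and all(
                        sum(a * b for a, b in zip(vec, cand)) == 0 for vec in kernel
                    )
                ):
                    w = cand
                    break
    if w is None:  # pragma: no cover - should not happen for integer input
        raise NetworkError("failed to certify dynamical triviality exactly")
    v = _exact.solve(gamma_t_rows, w)
    assert v is not None
    # verify
    gv = [sum(a * b for a, b in zip(row, v)) for row in gamma_t_rows]
    assert all(x >= 0 for x in gv) and any(x > 0 for x in gv)
    return tuple(v)


def kernel_sign_vector(net: Network) -> tuple[int, ...]:
    """Kernel spanning vector u = c x d for an m=3, rank-2 network.

    c and d are the first two linearly independent rows of Gamma, in species
    order.  The raw cross product is returned (no sign normalisation): the
    network is dynamically nontrivial iff all entries of u share one strict
    sign.
    """
    if net.m != 3:
        raise NetworkError("kernel_sign_vector requires exactly 3 reactions")
    rows = [list(row) for row in net.gamma.tolist()]
    if _exact.rank(rows) != 2:
        raise NetworkError("kernel_sign_vector requires rank 2")
    i, j = _exact.independent_rows(rows, 2)
    u = _exact.cross3(rows[i], rows[j])
    return tuple(int(x) for x in u)


def sources_collinear(net: Network) -> bool:
    """True iff all source complexes lie on one affine line in R^n."""
    pts = [r.source.coeffs for r in net.reactions]
    if len(pts) <= 2:
        return True
    diffs = [[p[i] - pts[0][i] for i in range(net.n)] for p in pts[1:]]
    return _exact.rank(diffs) <= 1


# ---------------------------------------------------------------------------
# canonical form
# ---------------------------------------------------------------------------


def _serialized(net: Network, perm: Sequence[int]) -> tuple:
    """Reactions as sorted (source, target) tuples under a species permutation."""
    keys = []
    for r in net.reactions:
        src = tuple(r.source.coeffs[p] for p in perm)
        tgt = tuple(r.target.coeffs[p] for p in perm)
        keys.append((src, tgt))
    return tuple(sorted(keys))


def canonical_key(net: Network) -> tuple:
    """Hashable canonical form: lexicographically minimal serialization
    over all species permutations, reactions sorted.  Two networks are
    isomorphic iff their keys are equal."""
    return min(
        _serialized(net, perm) for perm in itertools.permutations(range(net.n))
    )


def canonicalize(net: Network) -> Network:
    """Representative network of the isomorphism class of ``net``."""
    key = canonical_key(net)
    species = _default_species(net.n)
    reactions = tuple(
        Reaction(ComplexVec(src), ComplexVec(tgt)) for src, tgt in key
    )
    return Network(tuple(species), reactions)


def is_isomorphic(a: Network, b: Network) -> bool:
    return a.n == b.n and a.m == b.m and canonical_key(a) == canonical_key(b)


# ---------------------------------------------------------------------------
# trimolecularization
# ---------------------------------------------------------------------------


def trimolecularize(
    net: Network, kappa: Sequence[float] | None = None
) -> tuple[Network, list[float] | None]:
    """Rewrite high-molecularity targets as parallel single-species updates.

    Every reaction whose target has molecularity >= 4 is replaced by the (at
    most n) reactions  sum_i a_i X_i -> (a_j + sgn c_j) X_j + sum_{i!=j} a_i X_i
    at rate kappa*|c_j|, one for each species j with c_j != 0.  The induced
    mass-action vector fields are identical, so dynamical claims transfer at
    the cost of extra reactions and tied rate constants.
    """
    if not is_quadratic(net):
        raise NetworkError("trimolecularize requires a quadratic network")
    if kappa is not None and len(kappa) != net.m:
        raise NetworkError("kappa length mismatch")
    new_reactions: list[Reaction] = []
    new_kappa: list[float] = []
    for j, r in enumerate(net.reactions):
        k = 1 if kappa is None else kappa[j]  # keeps Fractions exact
        if r.target.molecularity <= 3:
            new_reactions.append(r)
            new_kappa.append(k)
            continue
        c = r.vector
        for i, ci in enumerate(c):
            if ci == 0:
                continue
            tgt = list(r.source.coeffs)
            tgt[i] += sign(ci)
            new_reactions.append(Reaction(r.source, ComplexVec(tuple(tgt))))
            new_kappa.append(k * abs(ci))
    out = Network(net.species, tuple(new_reactions))
    return out, (new_kappa if kappa is not None else None)
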