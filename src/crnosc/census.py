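"""Exhaustive enumeration of small quadratic networks and the censuses.

All counts are isomorphism-class counts (canonical forms under species
permutation and reaction reordering).  The oscillation census over
three-reaction quadratic trimolecular networks restricts candidate
generation using two facts that hold for every network admitting a
periodic orbit: the three source complexes must be affinely independent
(a rank-two system with collinear sources has no periodic orbit), and
every species must occur in some source complex (a species never consumed
makes the network dynamically trivial; a trivial species occurs in a
source by definition of appearing at all).  A pruning-soundness test
re-runs the planar census without these filters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

from . import _exact
from ._exact import sign
from .classify import (
    OSCILLATORY_OUTCOMES,
    CASE_TEMPLATES,
    Verdict,
    _case_hopf_conditions,
    classify_trimolecular_general,
    hopf_verdict_planar,
    identify_family,
)
from .network import (
    Network,
    canonical_key,
    is_dynamically_nontrivial,
    network_from_arrays,
    network_rank,
)


def enumerate_complexes(n: int, max_mol: int) -> list[tuple[int, ...]]:
    """All complexes on n species with molecularity <= max_mol, lex order."""
    if n < 1 or max_mol < 0:
        raise ValueError("need n >= 1 and max_mol >= 0")
    return [
        c
        for c in itertools.product(range(max_mol + 1), repeat=n)
        if sum(c) <= max_mol
    ]


@dataclass(frozen=True)
class EnumSpec:
    n_species: int
    n_reactions: int = 3
    max_source_mol: int = 2
    max_target_mol: int = 3
    require_rank: int | None = None
    require_nontrivial: bool = False
    allow_trivial_species: bool = True
    distinct_sources: bool = False


@dataclass
class CensusResult:
    count: int
    networks: list[Network] = field(default_factory=list)
    verdicts: list[Verdict] = field(default_factory=list)
    composition: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fast exact filter: rank two with strictly positive kernel
# ---------------------------------------------------------------------------


def _positive_kernel_rank2(g1, g2, g3) -> tuple[int, int, int] | None:
    """For integer columns g1, g2, g3: a positive integer kernel vector if
    the matrix [g1 g2 g3] has rank 2 and its kernel meets the open positive
    orthant, else None.  Exact integer arithmetic throughout."""
    n = len(g1)
    pair = None
    for r in range(n):
        for s in range(r + 1, n):
            det = g1[r] * g2[s] - g1[s] * g2[r]
            if det:
                pair = (r, s, det)
                break
        if pair:
            break
    if pair is None:  # g1 parallel to g2 -> rank <= 1 or no positive kernel
        return None
    r, s, det = pair
    a = -(g3[r] * g2[s] - g3[s] * g2[r])
    b = -(g1[r] * g3[s] - g1[s] * g3[r])
    sd = sign(det)
    if sign(a) != sd or sign(b) != sd:
        return None
    for i in range(n):
        if a * g1[i] + b * g2[i] + det * g3[i] != 0:
            return None
    return (a * sd, b * sd, det * sd)


def _affinely_independent(p1, p2, p3) -> bool:
    d1 = [x - y for x, y in zip(p2, p1)]
    d2 = [x - y for x, y in zip(p3, p1)]
    for r in range(len(d1)):
        for s in range(r + 1, len(d1)):
            if d1[r] * d2[s] - d1[s] * d2[r]:
                return True
    return False


# ---------------------------------------------------------------------------
# generic enumeration
# ---------------------------------------------------------------------------


def enumerate_networks(spec: EnumSpec, reverse: bool = False):
    """Yield one canonical representative per isomorphism class.

    Deterministic order; ``reverse`` flips the candidate iteration order
    (used to test order independence of the censuses).  Candidates where
    some species appears in no complex are skipped: those networks live in
    the enumeration for fewer species.
    """
    n = spec.n_species
    sources = enumerate_complexes(n, spec.max_source_mol)
    targets = enumerate_complexes(n, spec.max_target_mol)
    if reverse:
        sources = sources[::-1]
        targets = targets[::-1]
    seen: set = set()
    src_iter = (
        itertools.combinations(sources, spec.n_reactions)
        if spec.distinct_sources
        else itertools.combinations_with_replacement(sources, spec.n_reactions)
    )
    for srcs in src_iter:
        target_lists = [[t for t in targets if t != s] for s in srcs]
        for tgts in itertools.product(*target_lists):
            reactions = list(zip(srcs, tgts))
            if len(set(reactions)) != len(reactions):
                continue  # duplicate reactions
            support = [
                any(s[i] or t[i] for s, t in reactions) for i in range(n)
            ]
            if not all(support):
                continue
            if not spec.allow_trivial_species:
                if any(
                    all(t[i] == s[i] for s, t in reactions) for i in range(n)
                ):
                    continue
            cols = [tuple(t[i] - s[i] for i in range(n)) for s, t in reactions]
            if spec.require_rank is not None:
                if _exact.rank([list(c) for c in cols]) != spec.require_rank:
                    continue
            net = network_from_arrays(srcs, tgts)
            if spec.require_nontrivial and not is_dynamically_nontrivial(net).status:
                continue
            key = canonical_key(net)
            if key in seen:
                continue
            seen.add(key)
            yield net


# ---------------------------------------------------------------------------
# censuses
# ---------------------------------------------------------------------------


def census_source_cases() -> CensusResult:
    """Triples of distinct bimolecular planar source complexes not on a
    line, counted up to exchange of the two species."""
    complexes = enumerate_complexes(2, 2)
    classes: dict = {}
    examined = 0
    for triple in itertools.combinations(complexes, 3):
        examined += 1
        if not _affinely_independent(*triple):
            continue
        swapped = tuple(sorted((b, a) for a, b in triple))
        key = min(tuple(sorted(triple)), swapped)
        classes.setdefault(key, triple)
    return CensusResult(
        count=len(classes),
        meta={
            "examined_triples": examined,
            "noncollinear_unswapped": sum(
                1
                for t in itertools.combinations(complexes, 3)
                if _affinely_independent(*t)
            ),
            "representatives": sorted(classes),
        },
    )


def census_tetramolecular_hopf(
    max_target_mol: int = 4, compute_focal_values: bool = True
) -> CensusResult:
    """Planar three-reaction quadratic networks with target molecularity at
    most ``max_target_mol`` admitting an Andronov-Hopf bifurcation
    (supercritical or vertical), up to isomorphism.

    At the default bound four networks survive: 2X -> 3X+Y,
    X+Y -> (1+d)Y, Y -> 0 for d = 0..3, all with a supercritical
    bifurcation (first focal value < 0).  At bound 3 the census is empty.
    """
    sources = enumerate_complexes(2, 2)
    targets = enumerate_complexes(2, max_target_mol)
    seen: set = set()
    result = CensusResult(0)
    candidates = 0
    for srcs in itertools.combinations(sources, 3):
        if not _affinely_independent(*srcs):
            continue
        tlists = [[t for t in targets if t != s] for s in srcs]
        for tgts in itertools.product(*tlists):
            candidates += 1
            cols = [
                tuple(t[i] - s[i] for i in range(2)) for s, t in zip(srcs, tgts)
            ]
            if _positive_kernel_rank2(*cols) is None:
                continue
            net = network_from_arrays(srcs, tgts)
            key = canonical_key(net)
            if key in seen:
                continue
            seen.add(key)
            verdict = hopf_verdict_planar(net)
            if verdict.outcome in ("supercritical_hopf", "vertical_hopf"):
                result.networks.append(net)
                result.verdicts.append(verdict)
    result.count = len(result.networks)
    result.meta = {"candidates": candidates, "max_target_mol": max_target_mol}
    if compute_focal_values and result.networks:
        from .dynamics import MassActionSystem, positive_equilibria
        from .stability import find_hopf_kappa, first_focal_value

        focal = []
        for net in result.networks:
            fv = None
            for free in range(net.m):
                kappa = find_hopf_kappa(net, free_index=free)
                if kappa is None:
                    continue
                sys = MassActionSystem(net, kappa)
                x = positive_equilibria(sys).point_at().x
                fv = first_focal_value(sys, x)
                break
            focal.append(fv)
        result.meta["focal_values"] = focal
    return result


def census_figure1(max_species: int = 4) -> CensusResult:
    """All three-reaction quadratic trimolecular networks (any number of
    species, trivial species allowed) whose mass-action system admits a
    periodic orbit for some rate constants, up to isomorphism.

    The expected composition is: four generalized Lotka networks
    (c, d in {1, 2}), eight single-trivial-species augmentations of these,
    two double-trivial-species augmentations (the only four-species
    members), the Ivanova reactions, and the lifted LVA - 16 networks,
    of which only Lotka and Ivanova are bimolecular.
    """
    result = CensusResult(0)
    seen: set = set()
    candidates = 0
    per_n: dict[int, int] = {}
    for n in range(2, max_species + 1):
        found_n = 0
        sources = enumerate_complexes(n, 2)
        targets = enumerate_complexes(n, 3)
        for srcs in itertools.combinations(sources, 3):
            support = [any(s[i] for s in srcs) for i in range(n)]
            if not all(support):
                continue
            if not _affinely_independent(*srcs):
                continue
            s1, s2, s3 = srcs
            t1_list = [t for t in targets if t != s1]
            t2_list = [t for t in targets if t != s2]
            t3_list = [t for t in targets if t != s3]
            for t1 in t1_list:
                g1 = tuple(t1[i] - s1[i] for i in range(n))
                for t2 in t2_list:
                    g2 = tuple(t2[i] - s2[i] for i in range(n))
                    for t3 in t3_list:
                        candidates += 1
                        g3 = tuple(t3[i] - s3[i] for i in range(n))
                        if _positive_kernel_rank2(g1, g2, g3) is None:
                            continue
                        net = network_from_arrays(srcs, (t1, t2, t3))
                        key = canonical_key(net)
                        if key in seen:
                            continue
                        seen.add(key)
                        verdict = classify_trimolecular_general(net)
                        if verdict.oscillatory:
                            result.networks.append(net)
                            result.verdicts.append(verdict)
                            found_n += 1
        per_n[n] = found_n
    result.count = len(result.networks)
    comp: dict[str, int] = {}
    for v in result.verdicts:
        fam = v.family or "other"
        ntriv = len(v.removed_trivial_species)
        label = fam if ntriv == 0 else f"{fam}+{ntriv}_trivial"
        comp[label] = comp.get(label, 0) + 1
    result.composition = comp
    bimol = [
        net
        for net in result.networks
        if max(
            max(r.source.molecularity, r.target.molecularity)
            for r in net.reactions
        )
        <= 2
    ]
    from .network import trivial_species as _triv

    result.meta = {
        "candidates": candidates,
        "per_species_count": per_n,
        # the named bimolecular oscillators: bimolecular members without
        # trivial species (a trivial-species augmentation of one of these
        # can itself be bimolecular, hence the second count)
        "bimolecular": sum(1 for net in bimol if not _triv(net)),
        "bimolecular_including_trivial_augmentations": len(bimol),
    }
    return result


def case10_hopf_networks_at(max_target_mol: int) -> list[tuple]:
    """All (c1, d1, c3, d3) with sources 2X, X+Y, 0, targets bounded by
    ``max_target_mol``, satisfying the case-10 Hopf conditions."""
    out = []
    for c1 in range(1, max_target_mol - 1):
        for d1 in range(1, max_target_mol - 1 - c1 + 1):
            if 2 + c1 + d1 > max_target_mol:
                continue
            for c3 in range(1, max_target_mol + 1):
                for d3 in range(0, max_target_mol - c3 + 1):
                    if (
                        _case_hopf_conditions(
                            10, (c1, -1, c3), (d1, -1, d3)
                        )
                        == "supercritical_hopf"
                    ):
                        out.append((c1, d1, c3, d3))
    return out


def min_case10_molecularity(search_limit: int = 12) -> int:
    """Smallest target-molecularity bound at which a case-10 network
    (sources 2X, X+Y, 0) satisfies the Hopf conditions."""
    for mol in range(2, search_limit + 1):
        if case10_hopf_networks_at(mol):
            return mol
    raise RuntimeError(f"no case-10 Hopf network up to molecularity {search_limit}")


def supercritical_family_count(max_target_mol: int = 8) -> int:
    """Number of planar source cases admitting a supercritical Hopf
    bifurcation for some network with targets bounded by ``max_target_mol``."""
    cases = set()
    for cid, template in CASE_TEMPLATES.items():
        targets = enumerate_complexes(2, max_target_mol)
        tlists = [[t for t in targets if t != s] for s in template]
        found = False
        for tgts in itertools.product(*tlists):
            c = tuple(t[0] - s[0] for s, t in zip(template, tgts))
            d = tuple(t[1] - s[1] for s, t in zip(template, tgts))
            u = _exact.cross3(c, d)
            if not all(x > 0 for x in u):
                continue
            if _case_hopf_conditions(cid, c, d) == "supercritical_hopf":
                found = True
                break
        if found:
            cases.add(cid)
    return len(cases)


def min_reactions_for_oscillation(verify_by_simulation: bool = True) -> int:
    """Three reactions are necessary and sufficient for oscillation.

    Necessity: every dynamically nontrivial network with m <= 2 reactions
    has rank <= 1 (verified exhaustively over small planar networks), and
    periodic solutions need rank >= 2.  Sufficiency: the Lotka system has
    a periodic orbit (verified by the return-map test).
    """
    for m in (1, 2):
        spec = EnumSpec(
            n_species=2, n_reactions=m, max_source_mol=2, max_target_mol=3
        )
        for net in enumerate_networks(spec):
            if is_dynamically_nontrivial(net).status:
                if network_rank(net) > 1:  # pragma: no cover - impossible
                    raise AssertionError(
                        "nontrivial network with m <= 2 and rank > 1"
                    )
    if verify_by_simulation:
        from .classify import LOTKA
        from .dynamics import MassActionSystem, detect_periodicity

        sys = MassActionSystem(LOTKA, (1.0, 1.0, 1.0))
        res = detect_periodicity(sys, (2.0, 1.0), t_max=80.0)
        if res["periodic"] is not True:  # pragma: no cover
            raise AssertionError("Lotka orbit failed the periodicity test")
    return 3
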