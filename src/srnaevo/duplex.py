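"""Intermolecular RNA-RNA hybridization free energy and the mBS call.

The energy model is a nearest-neighbor duplex model restricted to
intermolecular structure (no intramolecular pairs, no accessibility):
Watson-Crick plus G:U pairs, a stacking-energy table for adjacent pairs,
a duplex initiation penalty, and an affine interior/bulge loop penalty
a + b*(n1 + n2) capped at total loop size L = 30.  Dangling ends and
terminal AU penalties are omitted by default; an additive terminal term
is configurable.

``duplex_energy`` is an O(n*m*L^2) dynamic program over "last pair"
states; ``brute_force_duplex_energy`` enumerates every antiparallel
non-crossing pairing on small inputs and is the test oracle.  An adapter
to the RNAduplex executable is provided for cross-checking only.

Presence of an mRNA binding site in an orthologous genome is decided by
the ratio rule: the site is present iff its duplex energy with the sRNA
site reaches at least 90% of the stability of the reference (E. coli)
interaction (dg_orth <= 0.9 * dg_ref; both energies negative).
"""

from __future__ import annotations

import functools
import json
import math
import subprocess
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "DuplexParams",
    "DuplexResult",
    "NO_DUPLEX",
    "default_params",
    "toy_params",
    "duplex_energy",
    "brute_force_duplex_energy",
    "mbs_call",
    "rnaduplex_energy",
]

_RNA_ALPHABET = set("ACGUN")
_CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)


class NoDuplex:
    """Sentinel: no admissible base pair between the two molecules."""

    def __repr__(self) -> str:
        return "NO_DUPLEX"

    def __bool__(self) -> bool:
        return False


NO_DUPLEX = NoDuplex()


def _revpair(p: tuple[str, str]) -> tuple[str, str]:
    return (p[1], p[0])


@dataclass(frozen=True)
class DuplexParams:
    """Nearest-neighbor duplex parameters (kcal/mol)."""

    pairs: frozenset = _CANONICAL_PAIRS
    stacks: tuple = ()  # tuple of ((pair1, pair2), energy), closed symmetrically
    initiation: float = 4.09
    loop_open: float = 4.0
    loop_per_nt: float = 0.3
    max_loop: int = 30
    terminal: float = 0.0  # optional additive per-duplex terminal term
    generic_stack: float = -0.6

    _table: dict = field(default=None, repr=False, compare=False)

    def stack_energy(self, p1: tuple[str, str], p2: tuple[str, str]) -> float:
        if self._table is None:
            object.__setattr__(self, "_table", dict(self.stacks))
        return self._table.get((p1, p2), self.generic_stack)

    def loop_energy(self, n1: int, n2: int) -> float:
        if (n1, n2) == (0, 0):
            raise ValueError("(0,0) is a stack, not a loop")
        if math.isinf(self.loop_open) or math.isinf(self.loop_per_nt):
            return math.inf
        return self.loop_open + self.loop_per_nt * (n1 + n2)


def _close_symmetric(stacks: dict) -> tuple:
    """Close a stack table under reverse-complement symmetry.

    The physical stack [p1 over p2] read from the other strand is
    [rev(p2) over rev(p1)]; both orientations must score identically.
    """
    out = {}
    for (p1, p2), e in stacks.items():
        mirror = (_revpair(p2), _revpair(p1))
        for key in ((p1, p2), mirror):
            if key in out and out[key] != e:
                raise ValueError(f"asymmetric stack table at {key}")
            out[key] = e
    return tuple(sorted(out.items()))


@functools.lru_cache(maxsize=1)
def default_params() -> DuplexParams:
    """Bundled Turner-style nearest-neighbor parameter subset."""
    raw = json.loads(
        resources.files("srnaevo.data").joinpath("nn_stacks.json").read_text()
    )
    stacks = {}
    for key, e in raw["stacks"].items():
        s1, s2 = key.split("/")
        stacks[((s1[0], s2[0]), (s1[1], s2[1]))] = float(e)
    return DuplexParams(
        stacks=_close_symmetric(stacks),
        initiation=raw["initiation"],
        loop_open=raw["loop_open"],
        loop_per_nt=raw["loop_per_nt"],
        max_loop=raw["max_loop"],
        generic_stack=raw["generic_stack"],
    )


def toy_params(stack: float = -2.0, initiation: float = 4.0,
               loop_open: float = math.inf, loop_per_nt: float = math.inf) -> DuplexParams:
    """Uniform-stack parameters for hand-checkable tests."""
    stacks = {
        (p1, p2): stack for p1 in _CANONICAL_PAIRS for p2 in _CANONICAL_PAIRS
    }
    return DuplexParams(
        stacks=tuple(sorted(stacks.items())),
        initiation=initiation,
        loop_open=loop_open,
        loop_per_nt=loop_per_nt,
        generic_stack=stack,
    )


@dataclass
class DuplexResult:
    """Minimum free energy and the pairing that achieves it."""

    dg: float | NoDuplex
    pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def interval_a(self) -> tuple[int, int] | None:
        if not self.pairs:
            return None
        return (min(i for i, _ in self.pairs), max(i for i, _ in self.pairs) + 1)

    @property
    def interval_b(self) -> tuple[int, int] | None:
        if not self.pairs:
            return None
        return (min(j for _, j in self.pairs), max(j for _, j in self.pairs) + 1)


def _validate_rna(seq: str, name: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-RNA characters: {sorted(bad)}")
    return seq


def _step_energy(
    params: DuplexParams,
    a: str, b: str,
    prev: tuple[int, int], cur: tuple[int, int],
) -> float:
    (i0, j0), (i1, j1) = prev, cur
    n1, n2 = i1 - i0 - 1, j0 - j1 - 1
    if (n1, n2) == (0, 0):
        return params.stack_energy((a[i0], b[j0]), (a[i1], b[j1]))
    if n1 + n2 > params.max_loop:
        return math.inf
    return params.loop_energy(n1, n2)


def duplex_energy(seq_a: str, seq_b: str, params: DuplexParams | None = None) -> DuplexResult:
    """Minimum free energy over all antiparallel non-crossing pairings.

    Both sequences are read 5'->3'; a pairing is an increasing sequence
    of positions on ``seq_a`` matched to a decreasing sequence on
    ``seq_b``.  Energy = initiation + sum of stack/loop step terms.
    Returns :data:`NO_DUPLEX` when no admissible pair exists.
    """
    if params is None:
        params = default_params()
    a = _validate_rna(seq_a, "seq_a")
    b = _validate_rna(seq_b, "seq_b")
    n, m = len(a), len(b)
    pair_ok = params.pairs
    L = params.max_loop

    candidates = [
        (i, j) for i in range(n) for j in range(m) if (a[i], b[j]) in pair_ok
    ]
    if not candidates:
        return DuplexResult(dg=NO_DUPLEX)

    init = params.initiation + params.terminal
    # E[(i, j)] = best energy of a duplex whose last (3'-most on a) pair is (i, j)
    E: dict[tuple[int, int], float] = {}
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    for i, j in sorted(candidates):
        best, arg = init, None
        for i0 in range(max(0, i - L - 1), i):
            for j0 in range(j + 1, min(m, j + L + 2)):
                prevE = E.get((i0, j0))
                if prevE is None:
                    continue
                step = _step_energy(params, a, b, (i0, j0), (i, j))
                if prevE + step < best:
                    best, arg = prevE + step, (i0, j0)
        E[(i, j)] = best
        back[(i, j)] = arg

    last = min(E, key=lambda k: E[k])
    pairs = []
    cur: tuple[int, int] | None = last
    while cur is not None:
        pairs.append(cur)
        cur = back[cur]
    pairs.reverse()
    return DuplexResult(dg=E[last], pairs=pairs)


def brute_force_duplex_energy(
    seq_a: str, seq_b: str, params: DuplexParams | None = None
) -> DuplexResult:
    """Exhaustive enumeration oracle; restricted to len(a)*len(b) <= 100."""
    if params is None:
        params = default_params()
    a = _validate_rna(seq_a, "seq_a")
    b = _validate_rna(seq_b, "seq_b")
    if len(a) * len(b) > 100:
        raise ValueError("input too large for brute-force enumeration")
    candidates = [
        (i, j)
        for i in range(len(a))
        for j in range(len(b))
        if (a[i], b[j]) in params.pairs
    ]
    if not candidates:
        return DuplexResult(dg=NO_DUPLEX)

    best_e = math.inf
    best_pairs: list[tuple[int, int]] = []

    def extend(chain: list[tuple[int, int]], energy: float) -> None:
        nonlocal best_e, best_pairs
        if energy < best_e:
            best_e, best_pairs = energy, list(chain)
        last = chain[-1]
        for nxt in candidates:
            if nxt[0] > last[0] and nxt[1] < last[1]:
                step = _step_energy(params, a, b, last, nxt)
                if math.isinf(step):
                    continue
                chain.append(nxt)
                extend(chain, energy + step)
                chain.pop()

    init = params.initiation + params.terminal
    for start in candidates:
        extend([start], init)
    return DuplexResult(dg=best_e, pairs=best_pairs)


def mbs_call(
    dg_orth: float | NoDuplex,
    dg_ref: float,
    ratio: float = 0.9,
    gap_flag: bool = False,
    ortholog_present: bool = True,
) -> int:
    """Call an orthologous mRNA binding site present (1) or absent (0).

    Present iff the ortholog exists, its aligned site has no gap over the
    core columns, and the duplex is at least ``ratio`` (default 90%) as
    stable as the reference interaction: dg_orth <= ratio * dg_ref
    (boundary inclusive; both energies negative).  NO_DUPLEX is absent.
    """
    if not dg_ref < 0:
        raise ValueError("reference duplex energy must be stabilizing (< 0)")
    if not ortholog_present or gap_flag:
        return 0
    if isinstance(dg_orth, NoDuplex):
        return 0
    return 1 if dg_orth <= ratio * dg_ref else 0


def rnaduplex_energy(seq_a: str, seq_b: str) -> float:
    """Energy from the external RNAduplex executable (cross-check only)."""
    out = subprocess.run(
        ["RNAduplex"],
        input=f"{seq_a}\n{seq_b}\n",
        capture_output=True,
        text=True,
        check=True,
    ).stdout
    # e.g. ".((((&)))).   1,4   :   3,6   (-5.40)"
    return float(out.strip().split("(")[-1].rstrip(")"))
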