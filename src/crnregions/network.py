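"""Reaction networks with mass-action kinetics.

A network is a list of species together with reactions

.. math::

    R_j:\\ \\sum_i \\alpha_{ij} X_i \\longrightarrow \\sum_i \\beta_{ij} X_i,

with non-negative integer coefficients.  From the network we derive the
stoichiometric matrix ``N`` (net production, ``N = beta - alpha``), a
row-reduced basis ``W`` of its left null space (the conservation
relations), and the mass-action ODE right-hand side ``f(x) = N v(x)``
with rate monomials ``v_j(x) = k_j prod_i x_i^alpha_ij``.

All linear algebra is exact: matrices are integer/rational sympy
matrices and ``W`` is canonicalized to reduced row-echelon form, which
makes the pivot indices (and everything built on them downstream)
deterministic.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import sympy as sp

__all__ = [
    "ReactionNetwork",
    "StoichiometricMatrix",
    "ConservationBasis",
    "MassActionSystem",
    "NoConservationRelations",
    "parse_network",
    "stoichiometric_matrix",
    "conservation_basis",
    "mass_action_system",
]

_NAME = r"[A-Za-z_][A-Za-z0-9_]*"
_TERM_RE = re.compile(rf"^\s*(\d+)?\s*\*?\s*({_NAME})\s*$")
_LABEL_RE = re.compile(r"\[([^\]]*)\]\s*$")


class NoConservationRelations(ValueError):
    """Raised when a network has full-rank ``N`` (``d = 0``).

    The partitioning procedure is built on the conservation relations
    (they define the stoichiometric compatibility classes), so it is not
    applicable to networks without them.
    """


def _parse_complex(text: str, order: list) -> dict:
    """Parse one side of a reaction into ``{species: coefficient}``."""
    text = text.strip()
    coeffs: dict = {}
    if text == "0":
        return coeffs
    for term in text.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ValueError(f"malformed term {term!r}")
        k = int(m.group(1)) if m.group(1) else 1
        if k <= 0:
            raise ValueError(f"non-positive coefficient in term {term!r}")
        name = m.group(2)
        if name not in order:
            order.append(name)
        coeffs[name] = coeffs.get(name, 0) + k
    return coeffs


@dataclass(frozen=True)
class ReactionNetwork:
    """A reaction network: species and integer reactant/product columns.

    ``alpha`` and ``beta`` are ``n x ell`` tuples of tuples (rows indexed
    by species, columns by reaction).  Reversible input arrows are stored
    as two irreversible reactions.  ``rate_names`` holds the symbol name
    of each reaction's rate constant (``k1..kℓ`` unless given
    explicitly).
    """

    species: tuple
    alpha: tuple
    beta: tuple
    rate_names: tuple

    def __post_init__(self):
        n, ell = self.n, self.ell
        for mat in (self.alpha, self.beta):
            if len(mat) != n or any(len(row) != ell for row in mat):
                raise ValueError("alpha/beta shape mismatch")
            if any(c < 0 or int(c) != c for row in mat for c in row):
                raise ValueError("stoichiometric coefficients must be non-negative integers")
        if len(set(self.species)) != n:
            raise ValueError("species names must be unique")
        for j in range(ell):
            if all(self.alpha[i][j] == self.beta[i][j] for i in range(n)):
                raise ValueError(f"reaction {j + 1} has identical reactant and product")

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def ell(self) -> int:
        return len(self.alpha[0]) if self.species else 0

    # -- convenience views ------------------------------------------------
    def reactant_support(self, j: int) -> frozenset:
        """Indices of species consumed by reaction ``j``."""
        return frozenset(i for i in range(self.n) if self.alpha[i][j] > 0)

    def product_support(self, j: int) -> frozenset:
        return frozenset(i for i in range(self.n) if self.beta[i][j] > 0)

    def reaction_text(self, j: int) -> str:
        def side(mat):
            terms = [
                (f"{mat[i][j]} " if mat[i][j] > 1 else "") + self.species[i]
                for i in range(self.n)
                if mat[i][j] > 0
            ]
            return " + ".join(terms) if terms else "0"

        return f"{side(self.alpha)} -> {side(self.beta)} [{self.rate_names[j]}]"

    def to_text(self) -> str:
        """Serialize back to the reaction-list grammar."""
        return "\n".join(self.reaction_text(j) for j in range(self.ell))

    def to_json(self) -> str:
        return json.dumps(
            {
                "species": list(self.species),
                "alpha": [list(r) for r in self.alpha],
                "beta": [list(r) for r in self.beta],
                "rate_names": list(self.rate_names),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ReactionNetwork":
        d = json.loads(text)
        return cls(
            tuple(d["species"]),
            tuple(tuple(r) for r in d["alpha"]),
            tuple(tuple(r) for r in d["beta"]),
            tuple(d["rate_names"]),
        )


def parse_network(
    text: str, species: Optional[Sequence[str]] = None
) -> ReactionNetwork:
    """Parse a newline- or semicolon-separated reaction list.

    Grammar: each reaction is ``lhs -> rhs`` or ``lhs <-> rhs`` where a
    side is ``0`` (empty complex) or a ``+``-separated list of terms
    ``Name``, ``2 Name`` or ``2*Name``.  An optional trailing
    ``[k_name]`` (or ``[k_fwd, k_rev]`` for reversible arrows) names the
    rate constant(s); otherwise constants are auto-named ``k1..kℓ`` in
    reaction order.  Species are ordered by first appearance unless an
    explicit ``species`` order is supplied.
    """
    order: list = list(species) if species is not None else []
    listed = frozenset(order)
    explicit = species is not None
    raw = [s for chunk in text.splitlines() for s in chunk.split(";")]
    reactions = []  # (reactant dict, product dict, label or None)
    for line in raw:
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        labels: list = []
        m = _LABEL_RE.search(line)
        if m:
            labels = [s.strip() for s in m.group(1).split(",") if s.strip()]
            line = line[: m.start()].rstrip()
        if "<->" in line:
            lhs, rhs = line.split("<->")
            a, b = _parse_complex(lhs, order), _parse_complex(rhs, order)
            if len(labels) not in (0, 2):
                raise ValueError(f"reversible reaction needs 2 labels: {line!r}")
            fwd = labels[0] if labels else None
            rev = labels[1] if labels else None
            reactions.append((a, b, fwd))
            reactions.append((b, a, rev))
        elif "->" in line:
            lhs, rhs = line.split("->")
            a, b = _parse_complex(lhs, order), _parse_complex(rhs, order)
            if len(labels) > 1:
                raise ValueError(f"irreversible reaction takes 1 label: {line!r}")
            reactions.append((a, b, labels[0] if labels else None))
        else:
            raise ValueError(f"malformed reaction {line!r}")
    if explicit:
        order = list(species)
        for a, b, _ in reactions:
            for name in list(a) + list(b):
                if name not in listed:
                    raise ValueError(f"species {name!r} not in the given order")
    n, ell = len(order), len(reactions)
    alpha = [[0] * ell for _ in range(n)]
    beta = [[0] * ell for _ in range(n)]
    names = []
    idx = {s: i for i, s in enumerate(order)}
    for j, (a, b, label) in enumerate(reactions):
        for s, c in a.items():
            alpha[idx[s]][j] = c
        for s, c in b.items():
            beta[idx[s]][j] = c
        names.append(label if label else f"k{j + 1}")
    seen = {}
    for j in range(ell):
        key = (
            tuple(alpha[i][j] for i in range(n)),
            tuple(beta[i][j] for i in range(n)),
        )
        if key in seen:
            warnings.warn(
                f"duplicate reaction {j + 1} (same as reaction {seen[key] + 1}); kept",
                stacklevel=2,
            )
        else:
            seen[key] = j
    net = ReactionNetwork(
        tuple(order),
        tuple(tuple(r) for r in alpha),
        tuple(tuple(r) for r in beta),
        tuple(names),
    )
    return net


@dataclass(frozen=True)
class StoichiometricMatrix:
    """The net-production matrix ``N = beta - alpha`` with its rank data.

    ``s = rank(N)`` and ``d = n - s`` (the corank, i.e. the number of
    independent conservation relations).
    """

    N: sp.Matrix
    s: int
    d: int


def stoichiometric_matrix(net: ReactionNetwork) -> StoichiometricMatrix:
    N = sp.Matrix(
        [[net.beta[i][j] - net.alpha[i][j] for j in range(net.ell)] for i in range(net.n)]
    )
    s = N.rank()
    return StoichiometricMatrix(N, s, net.n - s)


@dataclass(frozen=True)
class ConservationBasis:
    """Row-reduced rational basis ``W`` of the left null space of ``N``.

    ``W N = 0``, ``rank(W) = d``, and ``pivots`` records the (0-based)
    index of the first non-zero entry of each row.  The conservation
    relations read ``W x = c`` for class parameters ``c``.
    """

    W: sp.Matrix
    pivots: tuple

    @property
    def d(self) -> int:
        return self.W.rows


def conservation_basis(nmat: StoichiometricMatrix) -> ConservationBasis:
    """Canonical (RREF) conservation basis; raises if ``d = 0``."""
    if nmat.d == 0:
        raise NoConservationRelations(
            "no conservation relations; the partitioning procedure is not applicable"
        )
    kernel = nmat.N.T.nullspace()
    W = sp.Matrix([vec.T for vec in kernel]).rref()[0]
    pivots = tuple(
        min(j for j in range(W.cols) if W[i, j] != 0) for i in range(W.rows)
    )
    assert W * nmat.N == sp.zeros(W.rows, nmat.N.cols)
    return ConservationBasis(sp.Matrix(W), pivots)


@dataclass(frozen=True)
class MassActionSystem:
    """Symbolic mass-action ODE system ``x' = f(x) = N v(x)``.

    ``x`` are concentration symbols ``x1..xn`` in species order, ``kappa``
    the positive rate-constant symbols (one per reaction) and ``v`` the
    rate monomials.  Everything is exact sympy arithmetic.
    """

    network: ReactionNetwork
    x: tuple
    kappa: tuple
    v: tuple
    f: sp.Matrix = field(repr=False)

    @property
    def species_symbol(self) -> dict:
        """Map species name -> concentration symbol."""
        return dict(zip(self.network.species, self.x))


def mass_action_system(net: ReactionNetwork) -> MassActionSystem:
    n, ell = net.n, net.ell
    x = sp.symbols(f"x1:{n + 1}", positive=True)
    kappa = tuple(sp.Symbol(name, positive=True) for name in net.rate_names)
    if len(set(kappa)) != ell:
        raise ValueError("rate constant names must be distinct")
    v = []
    for j in range(ell):
        mono = kappa[j]
        for i in range(n):
            if net.alpha[i][j]:
                mono *= x[i] ** net.alpha[i][j]
        v.append(mono)
    N = stoichiometric_matrix(net).N
    f = N * sp.Matrix(v)
    return MassActionSystem(net, tuple(x), kappa, tuple(v), f)
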