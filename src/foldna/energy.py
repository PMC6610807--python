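"""Thermodynamic backend: structure evaluation, MFE folding, pair probabilities.

The built-in model is a deliberately simplified nearest-neighbour energy
function so the whole pipeline is testable without external binaries:

* canonical pairs only (Watson-Crick + GU wobble), hairpin loops of at least
  3 unpaired bases;
* stacking energies from a frozen 6x6 table (kcal/mol);
* hairpin and internal/bulge loop penalties ``a + b*ln(size)``;
* multiloops charged linearly: ``a + b*(branches) + c*(unpaired)`` with the
  closing pair counted as a branch;
* exterior bases free.

``mfe`` is a Zuker-style interval dynamic program over exactly this energy
function, and ``pair_probabilities`` runs McCaskill inside/outside recursions
under the same function, so the three operations are mutually consistent: the
Boltzmann weight of a structure in the partition function is
``exp(-eval_energy(s)/RT)``.  Interior loops are capped at
``max_interior_loop`` unpaired bases inside the dynamic programs (the
standard truncation); ``eval_energy`` itself scores any loop size.

Energies under this model are model-relative quantities: features computed
with different backends (e.g. the optional ViennaRNA adapter) are not
interchangeable, which is why trained models fingerprint the backend.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .structure_io import (
    CANONICAL_PAIRS,
    RnaSequence,
    SecondaryStructure,
    StructurePair,
    is_pseudoknotted,
)

__all__ = [
    "EnergyModel",
    "BasePairProbabilities",
    "EnergyError",
    "BackendError",
    "builtin_model",
    "eval_energy",
    "hairpin_penalty",
    "mfe",
    "pair_probabilities",
    "external_backend",
    "ViennaBackend",
]

log = logging.getLogger("foldna.energy")

INF = float("inf")


class EnergyError(ValueError):
    """Structure cannot be scored under the model (pseudoknot, bad loop, ...)."""


class BackendError(RuntimeError):
    """An external thermodynamics engine failed or is unavailable."""


@dataclass(frozen=True)
class EnergyModel:
    """Frozen parameter set for the built-in nearest-neighbour model."""

    name: str
    stacks: dict[str, dict[str, float]]
    hairpin_a: float
    hairpin_b: float
    min_hairpin: int
    internal_a: float
    internal_b: float
    multi_a: float
    multi_b: float
    multi_c: float
    temperature: float
    gas_constant: float
    max_interior_loop: int = 30

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature

    def stack_energy(self, outer: str, inner: str) -> float:
        return self.stacks[outer][inner]

    def hairpin(self, unpaired: int) -> float:
        if unpaired < self.min_hairpin:
            raise EnergyError(
                f"hairpin loop of {unpaired} < {self.min_hairpin} unpaired bases"
            )
        return self.hairpin_a + self.hairpin_b * math.log(unpaired)

    def internal(self, unpaired: int) -> float:
        # unpaired >= 1; unpaired == 0 is a stack, scored from the table
        return self.internal_a + self.internal_b * math.log(unpaired)

    def multiloop(self, branches: int, unpaired: int) -> float:
        return self.multi_a + self.multi_b * branches + self.multi_c * unpaired


def builtin_model(temperature: float | None = None) -> EnergyModel:
    """Load the frozen built-in parameter table (optionally overriding T)."""
    with resources.files("foldna.data").joinpath("builtin_energy_v1.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    return EnergyModel(
        name=cfg["version"],
        stacks=cfg["stacks"],
        hairpin_a=cfg["hairpin"]["a"],
        hairpin_b=cfg["hairpin"]["b"],
        min_hairpin=cfg["hairpin"]["min_unpaired"],
        internal_a=cfg["internal"]["a"],
        internal_b=cfg["internal"]["b"],
        multi_a=cfg["multiloop"]["a"],
        multi_b=cfg["multiloop"]["b_branch"],
        multi_c=cfg["multiloop"]["c_unpaired"],
        temperature=cfg["temperature_kelvin"] if temperature is None else temperature,
        gas_constant=cfg["gas_constant_kcal"],
        max_interior_loop=cfg["max_interior_loop"],
    )


@dataclass(frozen=True)
class BasePairProbabilities:
    """Equilibrium pairing probabilities ``p[i,j]`` and unpaired ``q[i]`` (1-based)."""

    n: int
    p: np.ndarray  # (n+1, n+1), entries at [i, j] for 1 <= i < j <= n
    q: np.ndarray  # (n+1,), entries at [i]

    def pair_prob(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return float(self.p[i, j])

    def unpaired_prob(self, i: int) -> float:
        return float(self.q[i])


# ---------------------------------------------------------------------------
# structure evaluation by loop decomposition
# ---------------------------------------------------------------------------


def _pair_name(seq: str, i: int, j: int) -> str:
    return seq[i - 1] + seq[j - 1]


def _check_canonical(seq: str, i: int, j: int) -> None:
    if (seq[i - 1], seq[j - 1]) not in CANONICAL_PAIRS:
        raise EnergyError(
            f"non-canonical pair {_pair_name(seq, i, j)} at ({i},{j}) "
            "cannot be scored by the energy model"
        )


def _loop_children(
    pairs: tuple[tuple[int, int], ...], i: int, j: int
) -> list[tuple[int, int]]:
    """Pairs directly accessible from (i, j) (no intermediate enclosing pair)."""
    inner = [(k, l) for (k, l) in pairs if i < k and l < j]
    out = []
    for k, l in inner:
        if not any(k2 < k and l < l2 for (k2, l2) in inner):
            out.append((k, l))
    return sorted(out)


def eval_energy(pair: StructurePair, model: EnergyModel) -> float:
    """Free energy (kcal/mol) of a pseudoknot-free structure by loop decomposition."""
    structure, seq = pair.structure, pair.sequence.residues
    if is_pseudoknotted(structure):
        raise EnergyError("pseudoknotted structure: decompose before scoring")
    pairs = structure.pairs
    for i, j in pairs:
        _check_canonical(seq, i, j)
    total = 0.0
    for i, j in pairs:
        children = _loop_children(pairs, i, j)
        if not children:
            total += model.hairpin(j - i - 1)
        elif len(children) == 1:
            (k, l) = children[0]
            unpaired = (k - i - 1) + (j - l - 1)
            if unpaired == 0:
                total += model.stack_energy(
                    _pair_name(seq, i, j), _pair_name(seq, k, l)
                )
            else:
                total += model.internal(unpaired)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += model.multiloop(len(children) + 1, unpaired)
    return total


def hairpin_penalty(pair_span: tuple[int, int], model: EnergyModel) -> float:
    """Hairpin-loop penalty of a hairpin closed by ``(i, j)``."""
    i, j = pair_span
    return model.hairpin(j - i - 1)


# ---------------------------------------------------------------------------
# MFE folding (interval dynamic programming with deterministic traceback)
# ---------------------------------------------------------------------------


def _can_pair(seq: str, i: int, j: int, min_hairpin: int) -> bool:
    return j - i - 1 >= min_hairpin and (seq[i - 1], seq[j - 1]) in CANONICAL_PAIRS


def _better(a: tuple[float, int], b: tuple[float, int]) -> bool:
    """True when candidate ``a`` beats ``b``: lower energy, then fewer pairs."""
    if a[0] < b[0] - 1e-12:
        return True
    if a[0] > b[0] + 1e-12:
        return False
    return a[1] < b[1]


def mfe(seq: RnaSequence, model: EnergyModel) -> tuple[float, SecondaryStructure]:
    """Minimum free energy and one optimal pseudoknot-free structure.

    Ties are broken toward fewer pairs, then by a fixed traceback scan order
    (earliest 5' pair, nearest partner) so the result is deterministic.
    """
    s = seq.residues
    n = len(s)
    mh = model.min_hairpin
    L = model.max_interior_loop
    bm, cm = model.multi_b, model.multi_c
    NEG = (INF, 0)

    # V[i][j]: best closed by pair (i, j); M[i][j]: >=1 branch in multiloop
    # context; M2[i][j]: >=2 branches.  Values are (energy, npairs).
    V = [[NEG] * (n + 2) for _ in range(n + 2)]
    M = [[NEG] * (n + 2) for _ in range(n + 2)]
    M2 = [[NEG] * (n + 2) for _ in range(n + 2)]

    for span in range(mh + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            # --- V
            if _can_pair(s, i, j, mh):
                best = (model.hairpin(j - i - 1), 1)
                outer = _pair_name(s, i, j)
                # stack / interior loop
                for k in range(i + 1, j):
                    if k - i - 1 > L:
                        break
                    for l in range(j - 1, k, -1):
                        u = (k - i - 1) + (j - l - 1)
                        if u > L:
                            break
                        vk = V[k][l]
                        if vk[0] == INF:
                            continue
                        cost = (
                            model.stack_energy(outer, _pair_name(s, k, l))
                            if u == 0
                            else model.internal(u)
                        )
                        cand = (cost + vk[0], 1 + vk[1])
                        if _better(cand, best):
                            best = cand
                # multiloop: closing pair is one branch
                m2 = M2[i + 1][j - 1]
                if m2[0] < INF:
                    cand = (model.multi_a + bm + m2[0], 1 + m2[1])
                    if _better(cand, best):
                        best = cand
                V[i][j] = best
            # --- M (>=1 branch, per-unpaired cost cm, per-branch cost bm)
            best = NEG
            if M[i + 1][j][0] < INF:
                best = (M[i + 1][j][0] + cm, M[i + 1][j][1])
            for l in range(i + mh + 1, j + 1):
                vi = V[i][l]
                if vi[0] == INF:
                    continue
                tail_open = (vi[0] + bm + cm * (j - l), vi[1])
                if _better(tail_open, best):
                    best = tail_open
                ml = M[l + 1][j] if l + 1 <= j else NEG
                if ml[0] < INF:
                    cand = (vi[0] + bm + ml[0], vi[1] + ml[1])
                    if _better(cand, best):
                        best = cand
            M[i][j] = best
            # --- M2 (first branch + >=1 more)
            best = NEG
            for k in range(i, j):
                for l in range(k + mh + 1, j):
                    vk = V[k][l]
                    if vk[0] == INF:
                        continue
                    ml = M[l + 1][j]
                    if ml[0] == INF:
                        continue
                    cand = (cm * (k - i) + vk[0] + bm + ml[0], vk[1] + ml[1])
                    if _better(cand, best):
                        best = cand
            M2[i][j] = best

    # exterior: W[i] = best over suffix i..n (unpaired exterior bases free)
    W: list[tuple[float, int]] = [(0.0, 0)] * (n + 2)
    for i in range(n, 0, -1):
        best = W[i + 1]
        for j in range(i + mh + 1, n + 1):
            vi = V[i][j]
            if vi[0] == INF:
                continue
            cand = (vi[0] + W[j + 1][0], vi[1] + W[j + 1][1])
            if _better(cand, best):
                best = cand
        W[i] = best

    # deterministic traceback
    pairs: list[tuple[int, int]] = []
    stack: list[tuple[str, int, int]] = [("W", 1, n)]

    def close_enough(a: float, b: float) -> bool:
        return abs(a - b) <= 1e-9

    while stack:
        kind, i, j = stack.pop()
        if kind == "W":
            while i <= n:
                tgt = W[i]
                if close_enough(tgt[0], W[i + 1][0]) and tgt[1] == W[i + 1][1]:
                    i += 1
                    continue
                hit = False
                for j2 in range(i + mh + 1, n + 1):
                    vi = V[i][j2]
                    if vi[0] == INF:
                        continue
                    if (
                        close_enough(vi[0] + W[j2 + 1][0], tgt[0])
                        and vi[1] + W[j2 + 1][1] == tgt[1]
                    ):
                        stack.append(("V", i, j2))
                        i = j2 + 1
                        hit = True
                        break
                if not hit:
                    i += 1
        elif kind == "V":
            pairs.append((i, j))
            tgt = V[i][j]
            if tgt[1] == 1 and close_enough(tgt[0], model.hairpin(j - i - 1)):
                continue
            outer = _pair_name(s, i, j)
            done = False
            for k in range(i + 1, j):
                if done or k - i - 1 > L:
                    break
                for l in range(j - 1, k, -1):
                    u = (k - i - 1) + (j - l - 1)
                    if u > L:
                        break
                    vk = V[k][l]
                    if vk[0] == INF:
                        continue
                    cost = (
                        model.stack_energy(outer, _pair_name(s, k, l))
                        if u == 0
                        else model.internal(u)
                    )
                    if close_enough(cost + vk[0], tgt[0]) and 1 + vk[1] == tgt[1]:
                        stack.append(("V", k, l))
                        done = True
                        break
            if done:
                continue
            m2 = M2[i + 1][j - 1]
            if m2[0] < INF and close_enough(model.multi_a + bm + m2[0], tgt[0]):
                stack.append(("M2", i + 1, j - 1))
        elif kind == "M2":
            tgt = M2[i][j]
            done = False
            for k in range(i, j):
                if done:
                    break
                for l in range(k + mh + 1, j):
                    vk = V[k][l]
                    if vk[0] == INF:
                        continue
                    ml = M[l + 1][j]
                    if ml[0] == INF:
                        continue
                    if (
                        close_enough(cm * (k - i) + vk[0] + bm + ml[0], tgt[0])
                        and vk[1] + ml[1] == tgt[1]
                    ):
                        stack.append(("V", k, l))
                        stack.append(("M", l + 1, j))
                        done = True
                        break
        elif kind == "M":
            tgt = M[i][j]
            if (
                M[i + 1][j][0] < INF
                and close_enough(M[i + 1][j][0] + cm, tgt[0])
                and M[i + 1][j][1] == tgt[1]
            ):
                stack.append(("M", i + 1, j))
                continue
            done = False
            for l in range(i + mh + 1, j + 1):
                vi = V[i][l]
                if vi[0] == INF:
                    continue
                if close_enough(vi[0] + bm + cm * (j - l), tgt[0]) and vi[1] == tgt[1]:
                    stack.append(("V", i, l))
                    done = True
                    break
                ml = M[l + 1][j] if l + 1 <= j else NEG
                if (
                    ml[0] < INF
                    and close_enough(vi[0] + bm + ml[0], tgt[0])
                    and vi[1] + ml[1] == tgt[1]
                ):
                    stack.append(("V", i, l))
                    stack.append(("M", l + 1, j))
                    done = True
                    break

    structure = SecondaryStructure(n=n, pairs=tuple(sorted(pairs)))
    return W[1][0], structure


# ---------------------------------------------------------------------------
# McCaskill partition function and base-pair probabilities
# ---------------------------------------------------------------------------


def pair_probabilities(seq: RnaSequence, model: EnergyModel) -> BasePairProbabilities:
    """Equilibrium base-pair probabilities by inside/outside recursions.

    Inside arrays mirror the MFE decomposition (closed pair / >=1-branch /
    >=2-branch multiloop segments, exterior chain); the outside pass
    propagates the probability of each closed pair through exterior,
    interior-loop and multiloop contexts.
    """
    s = seq.residues
    n = len(s)
    mh = model.min_hairpin
    L = model.max_interior_loop
    rt = model.rt
    bm = math.exp(-model.multi_b / rt)
    cm = math.exp(-model.multi_c / rt)
    closing = math.exp(-(model.multi_a + model.multi_b) / rt)

    Qb = np.zeros((n + 2, n + 2))
    Qm = np.zeros((n + 2, n + 2))
    Qm2 = np.zeros((n + 2, n + 2))

    def interior_weight(i: int, j: int, k: int, l: int) -> float:
        u = (k - i - 1) + (j - l - 1)
        if u == 0:
            e = model.stack_energy(_pair_name(s, i, j), _pair_name(s, k, l))
        else:
            e = model.internal(u)
        return math.exp(-e / rt)

    for span in range(mh + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            if _can_pair(s, i, j, mh):
                total = math.exp(-model.hairpin(j - i - 1) / rt)
                for k in range(i + 1, j):
                    if k - i - 1 > L:
                        break
                    for l in range(j - 1, k, -1):
                        if (k - i - 1) + (j - l - 1) > L:
                            break
                        if Qb[k, l] > 0.0:
                            total += interior_weight(i, j, k, l) * Qb[k, l]
                total += closing * Qm2[i + 1, j - 1]
                Qb[i, j] = total
            # Qm
            total = cm * Qm[i + 1, j]
            for l in range(i + mh + 1, j + 1):
                if Qb[i, l] > 0.0:
                    total += Qb[i, l] * bm * (cm ** (j - l) + Qm[l + 1, j])
            Qm[i, j] = total
            # Qm2
            total = 0.0
            for k in range(i, j):
                for l in range(k + mh + 1, j):
                    if Qb[k, l] > 0.0 and Qm[l + 1, j] > 0.0:
                        total += (cm ** (k - i)) * Qb[k, l] * bm * Qm[l + 1, j]
            Qm2[i, j] = total

    # exterior prefix/suffix partition functions (unpaired exterior free)
    Qext = np.ones(n + 2)  # Qext[j] = Z of prefix 1..j
    for j in range(1, n + 1):
        total = Qext[j - 1]
        for k in range(1, j - mh):
            if Qb[k, j] > 0.0:
                total += Qext[k - 1] * Qb[k, j]
        Qext[j] = total
    Qsuf = np.ones(n + 3)  # Qsuf[i] = Z of suffix i..n
    for i in range(n, 0, -1):
        total = Qsuf[i + 1]
        for j in range(i + mh + 1, n + 1):
            if Qb[i, j] > 0.0:
                total += Qb[i, j] * Qsuf[j + 1]
        Qsuf[i] = total
    Z = Qext[n]

    def qm_or_unpaired(x: int, y: int) -> float:
        """>=0 branches on [x, y] in multiloop context (empty segment -> 1)."""
        if x > y:
            return 1.0
        return Qm[x, y] + cm ** (y - x + 1)

    # outside pass, decreasing span
    P = np.zeros((n + 2, n + 2))
    spans = sorted(
        ((i, j) for i in range(1, n + 1) for j in range(i + mh + 1, n + 1) if Qb[i, j] > 0.0),
        key=lambda ij: ij[1] - ij[0],
        reverse=True,
    )
    for i, j in spans:
        # exterior context
        ext = Qext[i - 1] * Qb[i, j] * Qsuf[j + 1] / Z
        total = ext
        # interior-loop context under an enclosing pair (k, l)
        for k in range(max(1, i - L - 1), i):
            if i - k - 1 > L:
                continue
            for l in range(j + 1, min(n, j + L + 2 - (i - k - 1)) + 1):
                if (i - k - 1) + (l - j - 1) > L:
                    break
                if P[k, l] > 0.0 and _can_pair(s, k, l, mh):
                    total += (
                        P[k, l] / Qb[k, l] * interior_weight(k, l, i, j) * Qb[i, j]
                    )
        # multiloop branch context under enclosing pair (k, l)
        for k in range(1, i):
            for l in range(j + 1, n + 1):
                if P[k, l] <= 0.0:
                    continue
                left_branches = Qm[k + 1, i - 1] if k + 1 <= i - 1 else 0.0
                ways = left_branches * qm_or_unpaired(j + 1, l - 1)
                right = Qm[j + 1, l - 1] if j + 1 <= l - 1 else 0.0
                ways += (cm ** (i - k - 1)) * right
                if ways > 0.0:
                    total += P[k, l] / Qb[k, l] * closing * bm * Qb[i, j] * ways
        P[i, j] = total

    p = np.zeros((n + 1, n + 1))
    p[: n + 1, : n + 1] = P[: n + 1, : n + 1]
    q = np.ones(n + 1)
    for i in range(1, n + 1):
        q[i] = 1.0 - (p[i, :].sum() + p[:, i].sum())
    return BasePairProbabilities(n=n, p=p, q=q)


# ---------------------------------------------------------------------------
# external backend adapter (ViennaRNA seam)
# ---------------------------------------------------------------------------


class ViennaBackend:
    """Adapter delegating the three backend operations to ViennaRNA bindings.

    Provides the same surface as the built-in functions; energies are NOT
    interchangeable with built-in-model energies, so the fingerprint differs.
    """

    name = "viennarna"

    def __init__(self) -> None:
        try:
            import RNA  # type: ignore[import-not-found]
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise BackendError("ViennaRNA python bindings not importable") from exc
        self._rna = RNA
        self.name = f"viennarna-{getattr(RNA, '__version__', 'unknown')}"

    def eval_energy(self, pair: StructurePair) -> float:
        from .structure_io import to_dotbracket

        if is_pseudoknotted(pair.structure):
            raise EnergyError("pseudoknotted structure: decompose before scoring")
        fc = self._rna.fold_compound(pair.sequence.residues)
        return float(fc.eval_structure(to_dotbracket(pair.structure)))

    def mfe(self, seq: RnaSequence) -> tuple[float, SecondaryStructure]:
        from .structure_io import parse_dotbracket

        db, e = self._rna.fold(seq.residues)
        return float(e), parse_dotbracket(db)

    def pair_probabilities(self, seq: RnaSequence) -> BasePairProbabilities:
        fc = self._rna.fold_compound(seq.residues)
        fc.pf()
        bpp = np.array(fc.bpp())  # (n+1, n+1), 1-based upper triangle
        n = seq.n
        p = np.zeros((n + 1, n + 1))
        p[1 : n + 1, 1 : n + 1] = bpp[1:, 1:]
        q = np.ones(n + 1)
        for i in range(1, n + 1):
            q[i] = 1.0 - (p[i, :].sum() + p[:, i].sum())
        return BasePairProbabilities(n=n, p=p, q=q)


def external_backend(engine: str = "viennarna", strict: bool = False):
    """Return an external-engine adapter, or ``None`` to signal built-in fallback.

    With ``strict=False`` an absent engine degrades gracefully: a notice is
    logged and ``None`` is returned so callers use the built-in model.  With
    ``strict=True`` absence raises :class:`BackendError`.  A failure during a
    run is always raised, never silently replaced.
    """
    if engine != "viennarna":
        raise BackendError(f"unknown external engine {engine!r}")
    try:
        return ViennaBackend()
    except BackendError:
        if strict:
            raise
        log.warning("external engine %r unavailable; using built-in model", engine)
        return None
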