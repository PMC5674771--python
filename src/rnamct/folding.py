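"""Secondary-structure prediction backends behind one uniform contract.

Three backends are provided:

``reference``
    A built-in, fully deterministic maximum-base-pairing folder (Nussinov
    dynamic program over the six admissible pairs with a minimum hairpin
    loop of three unpaired bases).  It is self-contained and is the backend
    every test can rely on; it scores pair count, not free energy.
``vienna``
    RNAfold for nested structures, through the ViennaRNA Python bindings
    when importable, else the ``RNAfold`` CLI via subprocess.
``pkiss``
    pKiss for pseudoknotted structures, via subprocess.

Every prediction is canonicalized (parsed and re-rendered) before being
returned, and every backend counts its calls so fold budgets can be
audited.
"""

from __future__ import annotations

import shutil
import subprocess
from typing import Dict, Tuple, Type

from .structure_model import StructureError, parse_dotbracket

__all__ = [
    "FoldResult",
    "FoldBackend",
    "ReferenceBackend",
    "ViennaBackend",
    "PKissBackend",
    "BackendError",
    "get_backend",
    "PAIRABLE",
    "MIN_LOOP",
]

#: Admissible base pairs: Watson-Crick plus the GU wobble.
PAIRABLE = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: Minimum number of unpaired bases enclosed by a hairpin-closing pair.
MIN_LOOP = 3

_RNA_ALPHABET = frozenset("ACGU")


class BackendError(RuntimeError):
    """Raised when a folding engine is unavailable or misbehaves."""


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# symmetric 4x4 admissibility table for AU/UA, GC/CG, GU/UG
_PAIR_TABLE = [[False] * 4 for _ in range(4)]
for _a, _b in PAIRABLE:
    _PAIR_TABLE[_BASE_CODE[_a]][_BASE_CODE[_b]] = True


def _fill_dp(codes, n, min_loop, table):
    """Nussinov fill: M[i][j] = max pairs on the closed interval i..j."""
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            row = M[i + 1]
            best = row[j]
            ci = codes[i]
            for k in range(i + min_loop + 1, j + 1):
                if table[ci][codes[k]]:
                    cand = 1 + (row[k - 1] if k - 1 > i else 0) + (
                        M[k + 1][j] if k + 1 <= j else 0
                    )
                    if cand > best:
                        best = cand
            M[i][j] = best
    return M


try:  # JIT-compile the fill when numba is available; semantics identical
    import numpy as _np
    from numba import njit as _njit

    @_njit(cache=False)
    def _fill_dp_numba(codes, n, min_loop, table):  # pragma: no cover
        M = _np.zeros((n, n), dtype=_np.int32)
        for span in range(min_loop + 1, n):
            for i in range(n - span):
                j = i + span
                best = M[i + 1, j]
                ci = codes[i]
                for k in range(i + min_loop + 1, j + 1):
                    if table[ci, codes[k]]:
                        inner = M[i + 1, k - 1] if k - 1 > i else 0
                        rest = M[k + 1, j] if k + 1 <= j else 0
                        cand = 1 + inner + rest
                        if cand > best:
                            best = cand
                M[i, j] = best
        return M

    _NUMBA_TABLE = _np.array(_PAIR_TABLE, dtype=_np.bool_)
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class FoldResult:
    """A predicted structure, canonicalized, with its backend's name."""

    __slots__ = ("structure", "backend")

    def __init__(self, structure: str, backend: str) -> None:
        self.structure = structure
        self.backend = backend

    def __repr__(self) -> str:  # pragma: no cover
        return f"FoldResult({self.structure!r}, backend={self.backend!r})"


class FoldBackend:
    """Base class: validates input, canonicalizes output, counts calls."""

    name: str = "abstract"
    supports_pseudoknots: bool = False
    #: set by backends whose raw output is already in canonical form
    _emits_canonical: bool = False

    def __init__(self) -> None:
        self.call_count = 0

    def fold(self, sequence: str) -> FoldResult:
        if not sequence or not set(sequence) <= _RNA_ALPHABET:
            raise ValueError(f"sequence must be non-empty over ACGU: {sequence!r}")
        self.call_count += 1
        raw = self._predict(sequence)
        if len(raw) != len(sequence):
            raise BackendError(
                f"backend {self.name} returned structure of length "
                f"{len(raw)} for sequence of length {len(sequence)}"
            )
        if self._emits_canonical:
            return FoldResult(structure=raw, backend=self.name)
        try:
            canonical = parse_dotbracket(raw).dotbracket
        except StructureError as exc:
            raise BackendError(
                f"backend {self.name} returned unparsable structure: {exc}"
            ) from exc
        return FoldResult(structure=canonical, backend=self.name)

    def _predict(self, sequence: str) -> str:
        raise NotImplementedError

    def version(self) -> str:
        return "builtin"


class ReferenceBackend(FoldBackend):
    """Deterministic maximum-pairing folder (nested structures only).

    Dynamic program ``M[i][j]`` = maximum number of admissible pairs on the
    subsequence ``i..j`` with hairpin loops of at least :data:`MIN_LOOP`
    unpaired bases.  Traceback tie-breaking is fixed: if pairing the
    leftmost position of an interval attains the optimum it is paired, with
    the smallest admissible partner; otherwise it is left unpaired.  The
    same sequence therefore always folds to the same structure.
    """

    name = "reference"
    supports_pseudoknots = False
    _emits_canonical = True  # nested pairs rendered as '()' directly

    def __init__(self, max_length: int = 200) -> None:
        super().__init__()
        self.max_length = max_length

    def _predict(self, sequence: str) -> str:
        n = len(sequence)
        if n > self.max_length:
            raise BackendError(
                f"reference folder caps sequences at {self.max_length} nt "
                f"(got {n}); use an external backend for longer inputs"
            )
        s = sequence
        can_pair = lambda a, b: (s[a], s[b]) in PAIRABLE  # noqa: E731
        # M[i][j] over 0-based closed intervals; spans below MIN_LOOP+2 hold 0
        if _HAVE_NUMBA:
            codes = _np.array([_BASE_CODE[c] for c in s], dtype=_np.int8)
            M = _fill_dp_numba(codes, n, MIN_LOOP, _NUMBA_TABLE)
        else:
            codes = [_BASE_CODE[c] for c in s]
            M = _fill_dp(codes, n, MIN_LOOP, _PAIR_TABLE)
        pairs: list[Tuple[int, int]] = []
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j or j - i < MIN_LOOP + 1:
                continue
            target = M[i][j]
            paired = False
            for k in range(i + MIN_LOOP + 1, j + 1):
                if can_pair(i, k):
                    inner = M[i + 1][k - 1] if k - 1 > i + 1 else 0
                    rest = M[k + 1][j] if k + 1 < j else 0
                    if 1 + inner + rest == target:
                        pairs.append((i + 1, k + 1))
                        stack.append((i + 1, k - 1))
                        stack.append((k + 1, j))
                        paired = True
                        break
            if not paired:
                stack.append((i + 1, j))
        # traceback pairs are nested by construction: render '()' directly
        chars = ["."] * n
        for a, b in pairs:
            chars[a - 1] = "("
            chars[b - 1] = ")"
        return "".join(chars)


class ViennaBackend(FoldBackend):
    """RNAfold (nested MFE structures), bindings first, CLI fallback."""

    name = "vienna"
    supports_pseudoknots = False

    def __init__(self) -> None:
        super().__init__()
        self._rna = None
        try:
            import RNA  # type: ignore

            self._rna = RNA
        except ImportError:
            if shutil.which("RNAfold") is None:
                raise BackendError(
                    "vienna backend unavailable: neither the RNA Python "
                    "bindings nor the RNAfold executable were found"
                )

    def _predict(self, sequence: str) -> str:
        if self._rna is not None:
            structure, _energy = self._rna.fold(sequence)
            return structure
        proc = subprocess.run(
            ["RNAfold", "--noPS"],
            input=sequence + "\n",
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise BackendError(f"RNAfold failed: {proc.stderr.strip()}")
        return _extract_structure_line(proc.stdout, len(sequence), "RNAfold")

    def version(self) -> str:
        if self._rna is not None:
            return f"ViennaRNA bindings {getattr(self._rna, '__version__', '?')}"
        return "RNAfold CLI"


class PKissBackend(FoldBackend):
    """pKiss MFE prediction; the only backend that emits pseudoknots."""

    name = "pkiss"
    supports_pseudoknots = True

    def __init__(self, executable: str = "pKiss") -> None:
        super().__init__()
        self.executable = executable
        if shutil.which(executable) is None:
            raise BackendError(
                f"pkiss backend unavailable: executable {executable!r} not on PATH"
            )

    def _predict(self, sequence: str) -> str:
        proc = subprocess.run(
            [self.executable, "--mode", "mfe", sequence],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise BackendError(f"pKiss failed: {proc.stderr.strip()}")
        return _extract_structure_line(proc.stdout, len(sequence), "pKiss")

    def version(self) -> str:
        return f"{self.executable} CLI"


def _extract_structure_line(stdout: str, n: int, engine: str) -> str:
    """Pull the dot-bracket token of length n from an engine's stdout.

    Energy annotations and sequence echoes are discarded.
    """
    structure_chars = set(".()[]{}<>")
    for line in stdout.splitlines():
        for token in line.split():
            if len(token) == n and set(token) <= structure_chars:
                return token
    raise BackendError(
        f"could not locate a length-{n} structure line in {engine} output"
    )


_BACKENDS: Dict[str, Type[FoldBackend]] = {
    "reference": ReferenceBackend,
    "vienna": ViennaBackend,
    "pkiss": PKissBackend,
}


def get_backend(name: str, **kwargs) -> FoldBackend:
    """Instantiate a backend by name (``reference``, ``vienna``, ``pkiss``)."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ValueError(
            f"unknown backend {name!r}; choose from {sorted(_BACKENDS)}"
        ) from None
    return cls(**kwargs)
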