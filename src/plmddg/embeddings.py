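"""Per-residue embedding backends and the on-disk embedding cache.

A backend turns a mutation-centered :class:`~plmddg.windowing.SequenceWindow`
into an L x D matrix (one row per window position).  Three protein
language-model adapters are declared with their native widths — ESM-2
(1280), ESM-1v (1280), ProtTrans (1024) — and require external model
weights; a deterministic synthetic backend of configurable width serves
testing and simulation.

Channel inputs for the regressor can be the ``mutant`` window embedding,
the ``wildtype`` embedding, or their ``difference`` (mutant - wildtype;
the default).  The difference input is antisymmetric under reverse
augmentation — a reverse record's input is exactly the negation of its
forward partner's — matching the antisymmetry of the ddG label.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import AMINO_ACIDS, PAD_SYMBOL
from .errors import CacheIntegrityError, CapabilityError, ConfigurationError, ShapeError
from .windowing import SequenceWindow

CHANNEL_VARIANTS = ("difference", "mutant", "wildtype")


@dataclass(frozen=True)
class BackendSpec:
    """Declared identity of an embedding backend."""

    name: str
    dim: int
    deterministic: bool
    pad_policy: str = "zero_row"  # or "model_token"

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ConfigurationError(f"backend dim must be positive, got {self.dim}")
        if self.pad_policy not in ("zero_row", "model_token"):
            raise ConfigurationError(f"unknown pad policy {self.pad_policy!r}")


@dataclass
class EmbeddingMatrix:
    """L x D matrix of per-residue embeddings for one window."""

    values: np.ndarray
    backend_name: str
    window_key: tuple  # (complex_id, chain, position, variant, L)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError(f"embedding must be 2-D, got {self.values.ndim}-D")
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("embedding contains non-finite entries")


def residue_vectors(dim: int, seed: int) -> np.ndarray:
    """Fixed per-residue vector table f: 20 x dim, standard normal entries
    drawn once from seeded pseudo-randomness.  Row order follows the
    canonical amino-acid alphabet."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((len(AMINO_ACIDS), dim))


def positional_term(length: int, dim: int, scale: float = 0.1) -> np.ndarray:
    """Small deterministic positional component g(i) added to synthetic rows."""
    pos = np.arange(length)[:, None]
    j = np.arange(dim)[None, :]
    angle = pos / (50.0 ** (2 * (j // 2) / dim))
    out = np.where(j % 2 == 0, np.sin(angle), np.cos(angle))
    return scale * out


class SyntheticBackend:
    """Deterministic stand-in embedding producer.

    Row i = f(residue_i) + g(i), with f an injective per-residue table and
    g a fixed positional term.  Padding rows are all-zero under the
    ``zero_row`` policy, or g(i) alone under ``model_token`` (mimicking a
    model that embeds its unknown-residue token).
    """

    def __init__(self, dim: int = 64, seed: int = 0, pad_policy: str = "zero_row"):
        if dim < 8:
            raise ConfigurationError(f"synthetic dim must be >= 8, got {dim}")
        self.spec = BackendSpec(f"synthetic-{dim}-{seed}", dim, True, pad_policy)
        self.seed = seed
        self._table = residue_vectors(dim, seed)
        self._index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    @property
    def dim(self) -> int:
        return self.spec.dim

    def embed(self, window: SequenceWindow) -> EmbeddingMatrix:
        L = window.length
        g = positional_term(L, self.dim)
        rows = np.zeros((L, self.dim))
        for i, aa in enumerate(window.residues):
            if aa == PAD_SYMBOL:
                if self.spec.pad_policy == "model_token":
                    rows[i] = g[i]
                # zero_row: stays all-zero
            else:
                rows[i] = self._table[self._index[aa]] + g[i]
        cid, chain, pos = window.source
        return EmbeddingMatrix(
            rows, self.spec.name, (cid, chain, pos, window.variant, L)
        )


class _ExternalAdapter:
    """Adapter for a pretrained protein language model.

    The model weights are not bundled; instantiating is allowed (so specs
    and dims can be inspected) but embedding raises a capability error
    explaining how to enable the backend.  Padding symbols are passed to
    the model's unknown-residue token.
    """

    package_hint = ""

    def __init__(self, name: str, dim: int):
        self.spec = BackendSpec(name, dim, False, pad_policy="model_token")

    @property
    def dim(self) -> int:
        return self.spec.dim

    def embed(self, window: SequenceWindow) -> EmbeddingMatrix:
        raise CapabilityError(
            f"backend {self.spec.name!r} needs external model weights; "
            f"install {self.package_hint} and download the checkpoint, or use "
            f"the 'synthetic' backend for testing (synthetic output is never "
            f"substituted silently)"
        )


class Esm2Backend(_ExternalAdapter):
    package_hint = "fair-esm (esm2_t33_650M_UR50D)"

    def __init__(self) -> None:
        super().__init__("esm2", 1280)


class Esm1vBackend(_ExternalAdapter):
    package_hint = "fair-esm (esm1v_t33_650M_UR90S_1)"

    def __init__(self) -> None:
        super().__init__("esm1v", 1280)


class ProtTransBackend(_ExternalAdapter):
    package_hint = "transformers (prot_t5_xl_half_uniref50-enc)"

    def __init__(self) -> None:
        super().__init__("prottrans", 1024)


def get_backend(name: str, **kwargs):
    """Backend factory: esm2 | esm1v | prottrans | synthetic."""
    name = name.lower()
    if name == "synthetic":
        return SyntheticBackend(**kwargs)
    if kwargs:
        raise ConfigurationError(f"backend {name!r} takes no parameters")
    try:
        return {"esm2": Esm2Backend, "esm1v": Esm1vBackend,
                "prottrans": ProtTransBackend}[name]()
    except KeyError:
        raise ConfigurationError(f"unknown backend {name!r}") from None


def embed(window: SequenceWindow, backend) -> EmbeddingMatrix:
    """Embed one window, validating the declared width."""
    m = backend.embed(window)
    if m.values.shape != (window.length, backend.dim):
        raise ShapeError(
            f"backend {backend.spec.name!r} returned shape {m.values.shape}, "
            f"declared ({window.length}, {backend.dim})"
        )
    return m


def channel_input(
    wt_window: SequenceWindow,
    mut_window: SequenceWindow,
    backend,
    variant: str = "difference",
) -> np.ndarray:
    """The L x D matrix fed to one regressor channel for one record."""
    if variant not in CHANNEL_VARIANTS:
        raise ConfigurationError(f"unknown channel variant {variant!r}")
    if variant == "wildtype":
        return embed(wt_window, backend).values
    if variant == "mutant":
        return embed(mut_window, backend).values
    return embed(mut_window, backend).values - embed(wt_window, backend).values


def build_channel_arrays(
    records,
    sequences,
    length: int,
    backends,
    variant: str = "difference",
    cache: "EmbeddingCache | None" = None,
) -> list[np.ndarray]:
    """Stack per-record channel inputs: one (N, L, D_i) array per backend.

    When a cache is supplied, per-window embeddings are reused across
    records and runs.
    """
    from .windowing import window_batch  # local import avoids a cycle

    if variant not in CHANNEL_VARIANTS:
        raise ConfigurationError(f"unknown channel variant {variant!r}")
    pairs = window_batch(records, sequences, length)
    arrays = []
    for backend in backends:
        rows = []
        for wt, mut in pairs:
            if cache is None:
                rows.append(channel_input(wt, mut, backend, variant))
                continue
            mats = {}
            for win in (wt, mut):
                key = EmbeddingCache.key(win, backend.spec.name, backend.dim)
                m = cache.load(key)
                if m is None:
                    m = embed(win, backend)
                    cache.store(key, m)
                mats[win.variant] = m.values
            if variant == "wildtype":
                rows.append(mats["wildtype"])
            elif variant == "mutant":
                rows.append(mats["mutant"])
            else:
                rows.append(mats["mutant"] - mats["wildtype"])
        arrays.append(np.stack(rows))
    return arrays


# ---------------------------------------------------------------------------
# cache: one compressed .npz file per key under a directory

_CACHE_VERSION = 1


class EmbeddingCache:
    """Directory cache of embedding matrices, keyed by backend identity,
    width, window length/variant and a content hash of the window string."""

    def __init__(self, directory: str | Path):
        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)

    @staticmethod
    def key(matrix_or_window, backend_name: str, dim: int,
            residues: str | None = None) -> str:
        if isinstance(matrix_or_window, SequenceWindow):
            w = matrix_or_window
            variant, L, residues = w.variant, w.length, w.residues
        else:
            m = matrix_or_window
            _, _, _, variant, L = m.window_key
            if residues is None:
                raise ConfigurationError("residues required to key a matrix")
        digest = hashlib.sha256(residues.encode()).hexdigest()[:24]
        return f"{backend_name}_d{dim}_L{L}_{variant}_{digest}"

    def _path(self, key: str) -> Path:
        return self.dir / f"{key}.npz"

    def store(self, key: str, matrix: EmbeddingMatrix) -> None:
        meta = json.dumps(
            {
                "version": _CACHE_VERSION,
                "backend": matrix.backend_name,
                "window_key": list(matrix.window_key),
                "shape": list(matrix.values.shape),
            }
        )
        np.savez_compressed(
            self._path(key), values=matrix.values, meta=np.array(meta)
        )

    def load(self, key: str) -> EmbeddingMatrix | None:
        """Return the cached matrix, or None on a cache miss."""
        path = self._path(key)
        if not path.exists():
            return None
        try:
            with np.load(path, allow_pickle=False) as z:
                values = z["values"]
                meta = json.loads(str(z["meta"]))
        except Exception as exc:
            raise CacheIntegrityError(f"corrupt cache entry {path}: {exc}") from exc
        if list(values.shape) != meta["shape"]:
            raise CacheIntegrityError(f"cache entry {path}: shape mismatch")
        return EmbeddingMatrix(values, meta["backend"], tuple(meta["window_key"]))
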