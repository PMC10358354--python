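"""Domain translation: the pluggable translator interface and the CUT loss
mathematics.

The indoor-to-field pipeline treats the image translator as a black box that
maps a square RGB tile to a square RGB tile of the same size. Contrastive
unpaired translation (CUT) is the reference choice of translator: a one-sided
GAN whose generator is trained with an adversarial loss plus a patch-wise
contrastive (PatchNCE) loss tying each output patch to its co-located input
patch against N negatives. The loss functions are implemented here exactly
and are fully testable on plain vectors; network training itself lives behind
the external-adapter boundary (a trained generator is invoked as a
subprocess), because the pipeline only ever needs the mapping, not the
weights.

Two cheap built-in translators make the full pipeline runnable end-to-end
without any trained network: an identity map and a CIELAB8 mean-shift toward
reference statistics.
"""

from __future__ import annotations

import hashlib
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from . import colorspace
from .color import masked_means
from .masking import load_image, save_image

DEFAULT_TEMPERATURE = 0.07
DEFAULT_PROB_EPS = 1e-7


class TranslationError(RuntimeError):
    """An external translator failed or violated its contract."""


# ---------------------------------------------------------------------------
# Translator interface


@dataclass
class Translator:
    """Map from a square RGB tile to a same-size RGB tile.

    Calling the translator validates the contract on both sides: uint8 HxWx3
    in, identically-shaped uint8 out.
    """

    name: str
    fn: Callable[[np.ndarray], np.ndarray]
    deterministic: bool = True

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        if tile.ndim != 3 or tile.shape[2] != 3 or tile.dtype != np.uint8:
            raise ValueError(f"translator input must be uint8 HxWx3, got {tile.shape}")
        out = self.fn(tile)
        out = np.asarray(out)
        if out.shape != tile.shape:
            raise TranslationError(
                f"translator '{self.name}' returned shape {out.shape}, expected {tile.shape}"
            )
        if out.dtype != np.uint8:
            raise TranslationError(f"translator '{self.name}' returned dtype {out.dtype}")
        return out


def identity_translator() -> Translator:
    """Translator that returns its input unchanged (desk-scale stand-in)."""
    return Translator(name="identity", fn=lambda tile: tile.copy())


def stats_transfer_translator(
    reference_means: Sequence[float] = (170.0, 100.0, 160.0),
    strength: float = 1.0,
) -> Translator:
    """Shift a tile's CIELAB8 channel means toward reference statistics.

    A deterministic proxy for domain translation: the tile is converted to
    CIELAB8, every channel is offset by ``strength * (reference - mean)``,
    and the result converted back to RGB. ``strength=0`` is the identity.
    """
    if not (0.0 <= strength <= 1.0):
        raise ValueError(f"strength must be in [0, 1], got {strength}")
    ref = np.asarray(reference_means, dtype=np.float64)
    if ref.shape != (3,):
        raise ValueError("reference_means must have 3 channels")

    def _fn(tile: np.ndarray) -> np.ndarray:
        if strength == 0.0:
            return tile.copy()
        lab = colorspace.rgb_to_lab8(tile)
        full = np.ones(tile.shape[:2], dtype=bool)
        offsets = strength * (ref - masked_means(lab, full))
        shifted = colorspace.quantize(lab.astype(np.float64) + offsets)
        return colorspace.lab8_to_rgb(shifted)

    return Translator(name="stats_transfer", fn=_fn)


def external_translator_adapter(
    command_template: str,
    name: str = "external",
    workdir: str | Path | None = None,
    timeout: float | None = None,
) -> Translator:
    """Wrap an external program (e.g. a trained CUT generator checkpoint run
    through its inference script) as a Translator.

    ``command_template`` must contain ``{input}`` and ``{output}`` markers;
    the adapter writes the tile as PNG, substitutes the paths, runs the
    command, and reads the result back with shape/range validation. Results
    are cached on the tile's content hash, so repeated tiles do not re-invoke
    the program.
    """
    if "{input}" not in command_template or "{output}" not in command_template:
        raise ValueError("command template needs {input} and {output} markers")
    cache: dict[str, np.ndarray] = {}
    base = Path(workdir) if workdir is not None else None

    def _fn(tile: np.ndarray) -> np.ndarray:
        key = hashlib.sha256(tile.tobytes()).hexdigest() + f":{tile.shape}"
        if key in cache:
            return cache[key].copy()
        with tempfile.TemporaryDirectory(dir=base) as tmp:
            in_path = Path(tmp) / "in.png"
            out_path = Path(tmp) / "out.png"
            save_image(in_path, tile)
            cmd = command_template.format(input=str(in_path), output=str(out_path))
            try:
                subprocess.run(
                    cmd, shell=True, check=True, capture_output=True, timeout=timeout
                )
            except (subprocess.CalledProcessError, subprocess.TimeoutExpired) as exc:
                stderr = getattr(exc, "stderr", b"") or b""
                raise TranslationError(
                    f"external translator failed: {cmd!r}: {stderr.decode(errors='replace')}"
                ) from exc
            if not out_path.exists():
                raise TranslationError(f"external translator wrote no output: {cmd!r}")
            out = load_image(out_path)
        if out.shape != tile.shape:
            raise TranslationError(
                f"external translator returned shape {out.shape}, expected {tile.shape}"
            )
        cache[key] = out
        return out.copy()

    return Translator(name=name, fn=_fn)


# Registry so configs can select a translator by name.
_REGISTRY: dict[str, Callable[..., Translator]] = {
    "identity": identity_translator,
    "stats_transfer": stats_transfer_translator,
    "external": external_translator_adapter,
}


def get_translator(name: str, **options) -> Translator:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown translator '{name}'; known: {sorted(_REGISTRY)}") from None
    return factory(**options)


def register_translator(name: str, factory: Callable[..., Translator]) -> None:
    _REGISTRY[name] = factory


# ---------------------------------------------------------------------------
# CUT objective


@dataclass(frozen=True)
class FeaturePatchSet:
    """One PatchNCE comparison: a query feature, its positive, N negatives."""

    query: np.ndarray
    positive: np.ndarray
    negatives: np.ndarray  # (N, d)
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        q = np.asarray(self.query, dtype=np.float64)
        p = np.asarray(self.positive, dtype=np.float64)
        n = np.atleast_2d(np.asarray(self.negatives, dtype=np.float64))
        if q.ndim != 1 or p.shape != q.shape or n.shape[1] != q.shape[0]:
            raise ValueError("query/positive/negatives dimensions disagree")
        if n.shape[0] < 1:
            raise ValueError("need at least one negative sample")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        object.__setattr__(self, "query", q)
        object.__setattr__(self, "positive", p)
        object.__setattr__(self, "negatives", n)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the two PatchNCE terms in the total objective."""

    lambda_x: float = 1.0
    lambda_y: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_x < 0 or self.lambda_y < 0:
            raise ValueError("loss weights must be non-negative")


def patchnce_unit_loss(patches: FeaturePatchSet) -> float:
    """Cross-entropy of the positive patch among N+1 candidates.

    -log[ exp(q.p/t) / (exp(q.p/t) + sum_n exp(q.n/t)) ], evaluated in
    log-sum-exp stabilized form; always >= 0.
    """
    t = patches.temperature
    pos = float(patches.query @ patches.positive) / t
    negs = (patches.negatives @ patches.query) / t
    logits = np.concatenate(([pos], negs))
    return float(logsumexp(logits) - pos)


def patchnce_loss(feature_layers: Sequence[Sequence[FeaturePatchSet]]) -> float:
    """Sum of unit losses over all layers and spatial locations."""
    if len(feature_layers) == 0 or any(len(layer) == 0 for layer in feature_layers):
        raise ValueError("need at least one layer, each with at least one location")
    return float(
        sum(patchnce_unit_loss(ps) for layer in feature_layers for ps in layer)
    )


def adversarial_loss(
    d_real: np.ndarray, d_fake: np.ndarray, eps: float = DEFAULT_PROB_EPS
) -> float:
    """Non-saturating GAN value: E[log D(y)] + E[log(1 - D(G(x)))].

    Discriminator outputs are clipped to [eps, 1-eps] before the logs.
    """
    dr = np.clip(np.asarray(d_real, dtype=np.float64), eps, 1.0 - eps)
    df = np.clip(np.asarray(d_fake, dtype=np.float64), eps, 1.0 - eps)
    if dr.size == 0 or df.size == 0:
        raise ValueError("need at least one probability per batch")
    return float(np.mean(np.log(dr)) + np.mean(np.log1p(-df)))


def total_cut_loss(
    gan: float, nce_x: float, nce_y: float, weights: LossWeights = LossWeights()
) -> float:
    """Full objective: adversarial + lambda_X * NCE(X) + lambda_Y * NCE(Y).

    The second NCE term is the identity constraint, computed by the same
    PatchNCE machinery on target-domain features.
    """
    return gan + weights.lambda_x * nce_x + weights.lambda_y * nce_y
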