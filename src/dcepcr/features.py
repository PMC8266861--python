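"""Low-level convolutional feature extraction (pool2 contract).

Every extractor maps a 227 x 227 x 3 input to a 13 x 13 x 256 activation
stack — the shape of the second pooling layer of an AlexNet-style network —
flattened to a 43,264-length vector. Two backends are provided:

* ``"filterbank"`` (default): a deterministic bank of seeded random
  convolutions with two conv+ReLU+max-pool stages reproducing the
  227 -> 55 -> 27 -> 13 spatial ladder and 256 output channels. It needs
  no downloaded weights and is bit-for-bit reproducible.
* ``"alexnet-pool2"``: a plug-in slot for a pretrained AlexNet whose pool2
  layer emits 13 x 13 x 256 (the Caffe/MATLAB architecture). torchvision's
  AlexNet variant has a 192-channel pool2 and therefore fails the contract
  check; any backend claiming this name is contract-checked at load.

Flattening is row-major spatial with channel fastest:
``index = (row * 13 + col) * 256 + channel``. With both timepoints, the T1
block occupies indices 0..43,263 and the T2 block 43,264..86,527.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .imaging import ROI_SIZE, RoiPatch

__all__ = [
    "MAP_SHAPE",
    "FLAT_LEN",
    "T1T2_LEN",
    "ContractViolationError",
    "FeatureVector",
    "FilterBankExtractor",
    "CallableExtractor",
    "get_extractor",
    "prepare_input",
    "extract_features",
    "concat_timepoints",
    "flatten_index",
    "locate_feature",
]

MAP_SHAPE = (13, 13, 256)
FLAT_LEN = int(np.prod(MAP_SHAPE))  # 43,264 features per ROI
T1T2_LEN = 2 * FLAT_LEN  # 86,528 when T1 and T2 are combined


class ContractViolationError(RuntimeError):
    """An extractor did not produce a 13 x 13 x 256 activation stack."""


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-length feature representation of one patient."""

    values: np.ndarray
    patient_id: str
    timepoints: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", v)
        if len(v) not in (FLAT_LEN, T1T2_LEN):
            raise ValueError(f"feature vector length must be {FLAT_LEN} or {T1T2_LEN}")
        if not np.isfinite(v).all():
            raise ValueError("feature vector contains non-finite values")

    def __len__(self):
        return len(self.values)


def flatten_index(row: int, col: int, channel: int, timepoint_block: str = "T1") -> int:
    """Global feature index of activation-map cell (row, col, channel)."""
    if not (0 <= row < 13 and 0 <= col < 13 and 0 <= channel < 256):
        raise ValueError("activation coordinates out of range")
    idx = (row * 13 + col) * 256 + channel
    if timepoint_block == "T2":
        idx += FLAT_LEN
    elif timepoint_block != "T1":
        raise ValueError("timepoint_block must be 'T1' or 'T2'")
    return idx


def locate_feature(index: int):
    """Inverse of :func:`flatten_index`: ``(row, col, channel, block)``.

    Identifies which 13 x 13 activation map (channel) and which cell a
    selected feature belongs to — the basis of the visual-cue localization
    of selected optimal features.
    """
    if not 0 <= index < T1T2_LEN:
        raise ValueError(f"feature index must be in [0, {T1T2_LEN})")
    block = "T1" if index < FLAT_LEN else "T2"
    rem = index % FLAT_LEN
    spatial, channel = divmod(rem, 256)
    row, col = divmod(spatial, 13)
    return row, col, channel, block


def prepare_input(patch) -> tuple:
    """Replicate a grayscale patch to 3 channels and rescale to [0, 1].

    Returns ``(tensor, params)`` where ``params`` records the linear
    rescaling (vmin, vmax) applied; a constant patch maps to 0, keeping
    the zero patch a fixed point of the whole extraction chain.
    """
    img = patch.image if isinstance(patch, RoiPatch) else np.asarray(patch, float)
    if img.shape != (ROI_SIZE, ROI_SIZE):
        raise ValueError(f"expected a {ROI_SIZE}x{ROI_SIZE} patch")
    if not np.isfinite(img).all():
        raise ValueError("patch contains non-finite pixels")
    vmin, vmax = float(img.min()), float(img.max())
    if vmax > vmin:
        scaled = (img - vmin) / (vmax - vmin)
    else:
        scaled = np.zeros_like(img)
    return np.repeat(scaled[:, :, None], 3, axis=2), {"vmin": vmin, "vmax": vmax}


def _maxpool(x: np.ndarray, size: int = 3, stride: int = 2) -> np.ndarray:
    w = sliding_window_view(x, (size, size), axis=(0, 1))[::stride, ::stride]
    return w.max(axis=(-2, -1))


class FilterBankExtractor:
    """Deterministic seeded random-convolution backend.

    Two bias-free conv+ReLU+max-pool stages: 11x11 stride-4 convolutions
    (227 -> 55, pool to 27) over ``n_stage1`` channels, then 5x5 pad-2
    convolutions to 256 channels (27 -> 27, pool to 13). Zero input yields
    a zero vector; identical inputs yield identical vectors.
    """

    name = "filterbank"
    input_shape = (ROI_SIZE, ROI_SIZE, 3)
    output_shape = MAP_SHAPE
    flatten_order = "row-major spatial, channel fastest"

    def __init__(self, seed: int = 0, n_stage1: int = 8):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
        # unit-variance filters keep activations in a sane range
        self.w1 = rng.normal(0, 1, (11, 11, 3, n_stage1)) / np.sqrt(11 * 11 * 3)
        self.w2 = rng.normal(0, 1, (5, 5, n_stage1, 256)) / np.sqrt(5 * 5 * n_stage1)
        self.seed = int(seed)

    def activation_maps(self, tensor: np.ndarray) -> np.ndarray:
        if tensor.shape != self.input_shape:
            raise ValueError(f"expected input of shape {self.input_shape}")
        win = sliding_window_view(tensor, (11, 11, 3))[::4, ::4, 0]  # (55,55,11,11,3)
        a1 = np.maximum(np.einsum("xyijc,ijcf->xyf", win, self.w1), 0.0)
        p1 = _maxpool(a1)  # (27,27,n_stage1)
        pad = np.pad(p1, ((2, 2), (2, 2), (0, 0)))
        win2 = sliding_window_view(pad, (5, 5, p1.shape[2]))[:, :, 0]  # (27,27,5,5,k)
        a2 = np.maximum(np.einsum("xyijc,ijcf->xyf", win2, self.w2), 0.0)
        return _maxpool(a2)  # (13,13,256)

    def __call__(self, tensor: np.ndarray) -> np.ndarray:
        return self.activation_maps(tensor).reshape(-1)


class CallableExtractor:
    """Wrap any ``tensor -> (13, 13, 256)`` callable as a backend."""

    input_shape = (ROI_SIZE, ROI_SIZE, 3)
    output_shape = MAP_SHAPE
    flatten_order = "row-major spatial, channel fastest"

    def __init__(self, fn, name: str):
        self.fn = fn
        self.name = name

    def activation_maps(self, tensor: np.ndarray) -> np.ndarray:
        out = np.asarray(self.fn(tensor), dtype=float)
        if out.shape != MAP_SHAPE:
            raise ContractViolationError(
                f"backend '{self.name}' produced shape {out.shape}, "
                f"contract requires {MAP_SHAPE}")
        return out

    def __call__(self, tensor: np.ndarray) -> np.ndarray:
        return self.activation_maps(tensor).reshape(-1)


def _alexnet_pool2_backend():
    try:
        import torch
        import torchvision
    except ImportError as e:  # pragma: no cover - depends on optional extra
        raise ImportError(
            "the 'alexnet-pool2' backend needs torch/torchvision plus a "
            "pretrained AlexNet whose pool2 layer emits 13x13x256 (the "
            "Caffe/MATLAB architecture); install the 'torch' extra and "
            "supply such a model, or use the 'filterbank' backend") from e

    model = torchvision.models.alexnet(weights="IMAGENET1K_V1").features[:6].eval()

    def fn(tensor):
        with torch.no_grad():
            x = torch.from_numpy(np.ascontiguousarray(tensor.transpose(2, 0, 1))[None]).float()
            out = model(x)[0].numpy().transpose(1, 2, 0)
        return out

    return CallableExtractor(fn, "alexnet-pool2")


def get_extractor(backend: str = "filterbank", seed: int = 0, check: bool = True):
    """Instantiate a backend and verify the pool2 contract on a probe input."""
    if backend == "filterbank":
        ex = FilterBankExtractor(seed=seed)
    elif backend == "alexnet-pool2":
        ex = _alexnet_pool2_backend()
    elif callable(backend):
        ex = CallableExtractor(backend, getattr(backend, "__name__", "custom"))
    else:
        raise ValueError(f"unknown backend {backend!r}")
    if check:
        probe = np.random.default_rng(0).random(ex.input_shape)
        vec = ex(probe)
        if vec.shape != (FLAT_LEN,):
            raise ContractViolationError(
                f"backend '{ex.name}' probe output has length {vec.size}, "
                f"contract requires {FLAT_LEN}")
    return ex


def extract_features(patch, extractor, patient_id: str = "", timepoint: str = "T1") -> FeatureVector:
    """Run one ROI patch through a backend; returns a 43,264-length vector."""
    tensor, _ = prepare_input(patch)
    maps = extractor.activation_maps(tensor)
    if maps.shape != MAP_SHAPE:
        raise ContractViolationError(
            f"backend '{extractor.name}' produced shape {maps.shape}, "
            f"contract requires {MAP_SHAPE}")
    tp = patch.timepoint if isinstance(patch, RoiPatch) else timepoint
    return FeatureVector(values=maps.reshape(-1), patient_id=patient_id, timepoints=(tp,))


def concat_timepoints(v1: FeatureVector, v2: FeatureVector | None = None) -> FeatureVector:
    """Concatenate T1 and T2 vectors (T1 block first); identity if v2 is None."""
    if v2 is None:
        return v1
    if v1.patient_id != v2.patient_id:
        raise ValueError(f"patient mismatch: {v1.patient_id!r} vs {v2.patient_id!r}")
    if len(v1) != FLAT_LEN or len(v2) != FLAT_LEN:
        raise ValueError("both inputs must be single-timepoint vectors")
    return FeatureVector(values=np.concatenate([v1.values, v2.values]),
                         patient_id=v1.patient_id,
                         timepoints=v1.timepoints + v2.timepoints)
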