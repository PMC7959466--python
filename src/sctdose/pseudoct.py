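"""Pseudo-CT generation: intensity normalization, axial reslicing, the
conditional-GAN trainer/applier and exact inverse transforms.

The chain mirrors an MRI-to-CT image-translation workflow: CT intensities
are clipped to [−500, 1000] HU and MRI intensities to their per-volume
[1%, 99%] quantile range, both then stretched linearly to [−1, 1]; axial
slices are resampled to a square network size by bilinear interpolation;
a U-Net-style generator is trained against a patch discriminator with a
pixel (L1) plus adversarial loss; and the transforms are inverted after
inference to restore the HU range (values outside the clip interval are, by
design, irrecoverable).

The network backend is the package's own numpy implementation (see
``sctdose._nn``); training is single-sample (batch size one) and fully
deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import _nn
from .grids import ImageVolume, Modality

__all__ = [
    "NormalizationParams",
    "GanConfig",
    "GeneratorModel",
    "fit_normalize",
    "denormalize",
    "to_axial_slices",
    "from_axial_slices",
    "train_pix2pix",
    "generate_pseudo_ct",
]


@dataclass
class NormalizationParams:
    """Intensity normalization: clip then linear stretch to [−1, 1].

    ``fitted_bounds`` records the per-volume low/high actually used and is
    what the inverse transform consumes; for CT the bounds are the fixed
    clip interval, for MRI the fitted quantiles.
    """

    ct_clip: tuple[float, float] = (-500.0, 1000.0)
    mri_quantiles: tuple[float, float] = (0.01, 0.99)
    stretch_range: tuple[float, float] = (-1.0, 1.0)
    fitted_bounds: tuple[float, float] | None = None
    mri_exclude_background: bool = True  # quantiles over nonzero (in-FOV) voxels

    def __post_init__(self):
        for lo, hi in (self.ct_clip, self.mri_quantiles, self.stretch_range):
            if not lo < hi:
                raise ValueError("NormalizationParams: intervals must satisfy low < high")
        if self.fitted_bounds is not None and not self.fitted_bounds[0] < self.fitted_bounds[1]:
            raise ValueError("NormalizationParams: fitted bounds must satisfy low < high")


def fit_normalize(
    volume: ImageVolume, params: NormalizationParams | None = None
) -> tuple[ImageVolume, NormalizationParams]:
    """Clip and stretch a volume to [−1, 1]; returns the fitted parameters.

    CT-like volumes clip to the fixed HU interval; MRI volumes clip to their
    fitted quantile range (computed over nonzero voxels by default).
    """
    if params is None:
        params = NormalizationParams()
    if volume.is_ct_like():
        low, high = params.ct_clip
    else:
        vals = volume.data
        if params.mri_exclude_background:
            vals = vals[vals != 0]
            if vals.size == 0:
                raise ValueError("fit_normalize: MRI volume has no nonzero voxels")
        if np.ptp(vals) == 0:
            raise ValueError("fit_normalize: constant MRI volume, quantiles undefined")
        qlo, qhi = params.mri_quantiles
        low, high = (float(q) for q in np.quantile(vals, [qlo, qhi]))
        if not low < high:
            raise ValueError("fit_normalize: degenerate quantile range")
    fitted = NormalizationParams(
        ct_clip=params.ct_clip,
        mri_quantiles=params.mri_quantiles,
        stretch_range=params.stretch_range,
        fitted_bounds=(low, high),
        mri_exclude_background=params.mri_exclude_background,
    )
    slo, shi = params.stretch_range
    clipped = np.clip(volume.data, low, high)
    normalized = (clipped - low) / (high - low) * (shi - slo) + slo
    return volume.with_data(normalized), fitted


def denormalize(volume: ImageVolume, fitted: NormalizationParams) -> ImageVolume:
    """Exact inverse of :func:`fit_normalize` on the clip interval.

    Inputs outside the stretch range map to the corresponding clip bound.
    """
    if fitted.fitted_bounds is None:
        raise ValueError("denormalize: fitted bounds missing; normalize first")
    low, high = fitted.fitted_bounds
    slo, shi = fitted.stretch_range
    x = np.clip(volume.data, slo, shi)
    return volume.with_data((x - slo) / (shi - slo) * (high - low) + low)


# ---------------------------------------------------------------------------
# axial reslicing
# ---------------------------------------------------------------------------


def _plane_coords(n_src: int, n_dst: int) -> np.ndarray:
    """FOV-preserving 1D resampling coordinates (pixel-center aligned)."""
    return (np.arange(n_dst) + 0.5) * (n_src / n_dst) - 0.5


def to_axial_slices(volume: ImageVolume, slice_size: int) -> np.ndarray:
    """Resample every axial (y, x) plane to ``slice_size``² bilinearly.

    The physical field of view is preserved; the result is an array of
    shape (nz, slice_size, slice_size) in ascending-z order.
    """
    nz, ny, nx = volume.shape
    if (ny, nx) == (slice_size, slice_size):
        return volume.data.copy()
    cy = _plane_coords(ny, slice_size)
    cx = _plane_coords(nx, slice_size)
    zz, yy, xx = np.meshgrid(np.arange(nz, dtype=float), cy, cx, indexing="ij")
    return ndimage.map_coordinates(volume.data, [zz, yy, xx], order=1, mode="nearest")


def from_axial_slices(slices: np.ndarray, reference: ImageVolume) -> ImageVolume:
    """Invert :func:`to_axial_slices` back onto the reference in-plane grid."""
    slices = np.asarray(slices, dtype=float)
    nz, ny, nx = reference.shape
    if slices.ndim != 3 or slices.shape[0] != nz:
        raise ValueError(
            f"from_axial_slices: expected {nz} slices, got array of shape {slices.shape}"
        )
    s = slices.shape[1]
    if slices.shape[1] != slices.shape[2]:
        raise ValueError("from_axial_slices: slices must be square")
    if (ny, nx) == (s, s):
        data = slices.copy()
    else:
        # inverse mapping: the target plane (ny, nx) samples the slice grid
        cy = _plane_coords(s, ny)
        cx = _plane_coords(s, nx)
        zz, yy, xx = np.meshgrid(np.arange(nz, dtype=float), cy, cx, indexing="ij")
        data = ndimage.map_coordinates(slices, [zz, yy, xx], order=1, mode="nearest")
    return reference.with_data(data)


# ---------------------------------------------------------------------------
# conditional GAN
# ---------------------------------------------------------------------------


@dataclass
class GanConfig:
    """Trainer configuration.

    ``generator_depth`` counts resolution levels (downsamplings) of the
    U-Net-style generator; ``discriminator_patch`` is the decision-grid size
    the patch discriminator produces at a 256² slice (the grid scales
    proportionally at other slice sizes). The paper-scale setting is
    slice 256 / depth 7 / 300 epochs; the defaults here are desk-scale for
    fast experimentation and testing.
    """

    generator_depth: int = 5
    discriminator_patch: int = 16
    slice_size: int = 64
    epochs: int = 20
    batch_size: int = 1
    pixel_loss_weight: float = 100.0
    base_filters: int = 8
    learning_rate: float = 2e-4
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        s = self.slice_size
        if s <= 0 or (s & (s - 1)) != 0:
            raise ValueError("GanConfig: slice_size must be a power of two")
        if s < 2**self.generator_depth:
            raise ValueError(
                f"GanConfig: slice_size {s} is too small for generator_depth "
                f"{self.generator_depth} ({s} < 2^{self.generator_depth}); "
                "reduce the depth or raise the slice size"
            )
        if self.batch_size != 1:
            raise ValueError("GanConfig: training is single-sample (batch_size must be 1)")
        if self.epochs < 1:
            raise ValueError("GanConfig: epochs must be >= 1")

    @property
    def patch_grid(self) -> int:
        """Discriminator output grid at this slice size."""
        return max(1, self.slice_size * self.discriminator_patch // 256)


def _build_generator(config: GanConfig, rng) -> tuple[list, list]:
    """Encoder/decoder block lists for the U-Net-style generator."""
    depth, base = config.generator_depth, config.base_filters
    enc_ch = [min(base * 2**i, base * 8) for i in range(depth)]
    enc = []
    c_in = 1
    for i, c_out in enumerate(enc_ch):
        layers = [_nn.Conv2d(c_in, c_out, k=4, stride=2, pad=1, rng=rng)]
        if 0 < i < depth - 1:
            layers.append(_nn.InstanceNorm(c_out))
        layers.append(_nn.LeakyReLU(0.2))
        enc.append(_nn.Sequential(*layers))
        c_in = c_out
    dec = []
    for j in range(depth - 1, 0, -1):
        in_ch = enc_ch[j] if j == depth - 1 else enc_ch[j] + enc_ch[j]
        out_ch = enc_ch[j - 1]
        dec.append(
            _nn.Sequential(
                _nn.Upsample2x(),
                _nn.Conv2d(in_ch, out_ch, k=3, stride=1, pad=1, rng=rng),
                _nn.InstanceNorm(out_ch),
                _nn.ReLU(),
            )
        )
    dec.append(
        _nn.Sequential(
            _nn.Upsample2x(),
            _nn.Conv2d(2 * enc_ch[0], 1, k=3, stride=1, pad=1, rng=rng),
            _nn.Tanh(),
        )
    )
    return enc, dec


def _build_discriminator(config: GanConfig, rng) -> _nn.Sequential:
    """Patch discriminator: stride-2 stack down to the decision grid."""
    n_down = int(math.log2(config.slice_size // config.patch_grid))
    base = config.base_filters
    layers = []
    c_in = 2  # conditioned on the MRI slice: (mri, ct) channel pair
    for i in range(n_down):
        c_out = min(base * 2**i, base * 8)
        layers.append(_nn.Conv2d(c_in, c_out, k=4, stride=2, pad=1, rng=rng))
        if i > 0:
            layers.append(_nn.InstanceNorm(c_out))
        layers.append(_nn.LeakyReLU(0.2))
        c_in = c_out
    layers.append(_nn.Conv2d(c_in, 1, k=3, stride=1, pad=1, rng=rng))
    return _nn.Sequential(*layers)


class GeneratorModel:
    """A trained (or freshly initialized) generator with its config.

    ``predict`` maps a normalized [−1, 1] slice to a normalized slice; the
    skip connections concatenate each encoder activation with the matching
    decoder resolution. Output is tanh-bounded to [−1, 1].
    """

    def __init__(self, config: GanConfig, rng=None):
        self.config = config
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.encoder, self.decoder = _build_generator(config, rng)
        self.loss_history: list[dict] = []
        self._skips: list = []

    @property
    def params(self):
        out = []
        for block in self.encoder + self.decoder:
            out.extend(block.params)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        acts = []
        h = x
        for block in self.encoder:
            h = block.forward(h)
            acts.append(h)
        self._skips = acts
        h = acts[-1]
        depth = self.config.generator_depth
        for stage, block in enumerate(self.decoder):
            h = block.forward(h)
            j = depth - 2 - stage  # encoder level concatenated next
            if j >= 0:
                h = np.concatenate([h, acts[j]], axis=0)
        return h

    def backward(self, dy: np.ndarray) -> None:
        depth = self.config.generator_depth
        dskips: list = [None] * depth
        d = dy
        for stage in range(len(self.decoder) - 1, -1, -1):
            j = depth - 2 - stage  # encoder level concatenated after this block
            if j >= 0:
                # split the concatenated gradient before entering the block
                c_skip = self._skips[j].shape[0]
                dskips[j] = d[-c_skip:].copy()
                d = d[:-c_skip]
            d = self.decoder[stage].backward(d)
        # d is now the gradient w.r.t. the bottleneck activation
        dskips[depth - 1] = d
        grad = None
        for i in range(depth - 1, -1, -1):
            total = dskips[i] if grad is None else grad + dskips[i]
            grad = self.encoder[i].backward(total)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.ascontiguousarray(x, dtype=_nn.DTYPE))

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params)}
        np.savez(directory / "weights.npz", **arrays)
        manifest = {"gan_config": asdict(self.config), "loss_history": self.loss_history}
        (directory / "model.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory) -> "GeneratorModel":
        directory = Path(directory)
        manifest = json.loads((directory / "model.json").read_text())
        cfg_dict = manifest["gan_config"]
        config = GanConfig(**cfg_dict)
        model = cls(config)
        with np.load(directory / "weights.npz") as data:
            for i, p in enumerate(model.params):
                p.value[...] = data[f"p{i}"]
        model.loss_history = manifest.get("loss_history", [])
        return model


def _check_normalized(arr: np.ndarray, what: str) -> None:
    if arr.min() < -1.001 or arr.max() > 1.001:
        raise ValueError(
            f"train_pix2pix: {what} contains values outside [-1.001, 1.001]; "
            "normalize slices before training"
        )


def train_pix2pix(pairs, config: GanConfig) -> GeneratorModel:
    """Train the generator adversarially on (mri, ct) normalized slice pairs.

    Per sample the discriminator takes one Adam step on real-vs-generated
    patch decisions, then the generator takes one step on the adversarial
    plus L1 pixel loss (weight ``pixel_loss_weight``). The per-epoch mean
    pixel loss, adversarial losses and discriminator loss are logged in
    ``model.loss_history``. Deterministic for a fixed ``config.seed``.
    """
    pairs = [
        (np.ascontiguousarray(m, dtype=_nn.DTYPE), np.ascontiguousarray(c, dtype=_nn.DTYPE))
        for m, c in pairs
    ]
    if not pairs:
        raise ValueError("train_pix2pix: at least one slice pair is required")
    s = config.slice_size
    for m, c in pairs:
        if m.shape != (s, s) or c.shape != (s, s):
            raise ValueError(
                f"train_pix2pix: slices must be {s}x{s}, got {m.shape} / {c.shape}"
            )
        _check_normalized(m, "an MRI slice")
        _check_normalized(c, "a CT slice")

    rng = np.random.default_rng(config.seed)
    model = GeneratorModel(config, rng=rng)
    disc = _build_discriminator(config, rng)
    opt_g = _nn.Adam(model.params, lr=config.learning_rate)
    opt_d = _nn.Adam(disc.params, lr=config.learning_rate)
    lam = config.pixel_loss_weight

    for epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        ep = {"pixel_l1": 0.0, "g_adv": 0.0, "d_loss": 0.0}
        for idx in order:
            mri, ct = pairs[idx]
            x = mri[None, :, :]
            y = ct[None, :, :]
            fake = model.forward(x)

            # --- discriminator step (generated slice detached) ---
            opt_d.zero_grad()
            z_real = disc.forward(np.concatenate([x, y], axis=0))
            loss_real = _nn.bce_with_logits(z_real, 1.0)
            disc.backward(0.5 * _nn.bce_with_logits_grad(z_real, 1.0))
            z_fake = disc.forward(np.concatenate([x, fake], axis=0))
            loss_fake = _nn.bce_with_logits(z_fake, 0.0)
            disc.backward(0.5 * _nn.bce_with_logits_grad(z_fake, 0.0))
            opt_d.step()

            # --- generator step: adversarial + L1 pixel loss ---
            opt_g.zero_grad()
            z = disc.forward(np.concatenate([x, fake], axis=0))
            g_adv = _nn.bce_with_logits(z, 1.0)
            dz = _nn.bce_with_logits_grad(z, 1.0)
            d_input = disc.backward(dz)  # disc grads discarded (not stepped)
            diff = fake - y
            pixel_l1 = float(np.abs(diff).mean())
            dfake = d_input[1:2] + lam * np.sign(diff).astype(_nn.DTYPE) / diff.size
            model.backward(dfake)
            opt_g.step()

            ep["pixel_l1"] += pixel_l1
            ep["g_adv"] += g_adv
            ep["d_loss"] += 0.5 * (loss_real + loss_fake)
        n = len(pairs)
        model.loss_history.append(
            {"epoch": epoch + 1, **{k: v / n for k, v in ep.items()}}
        )
    return model


def generate_pseudo_ct(
    model,
    mri: ImageVolume,
    mri_params: NormalizationParams | None = None,
    ct_params: NormalizationParams | None = None,
) -> ImageVolume:
    """MRI volume → pseudo-CT: normalize, slice, infer, reassemble, invert.

    The inverse stretch uses the CT clip bounds, so the output HU range is
    contained in the clip interval by construction. Geometry is preserved
    and the result is tagged PSEUDO_CT.
    """
    config = getattr(model, "config", None)
    slice_size = config.slice_size if config is not None else mri.shape[1]
    normalized, _ = fit_normalize(mri, mri_params)
    slices = to_axial_slices(normalized, slice_size)
    out_slices = np.empty_like(slices)
    for i in range(slices.shape[0]):
        pred = model.predict(slices[i][None, :, :])
        pred = np.asarray(pred)
        if pred.ndim == 3:
            pred = pred[0]
        if pred.shape != slices[i].shape:
            raise ValueError(
                f"generate_pseudo_ct: model produced shape {pred.shape} for a "
                f"{slices[i].shape} slice; slice_size mismatch"
            )
        out_slices[i] = pred
    reassembled = from_axial_slices(out_slices, mri)
    if ct_params is None:
        ct_params = NormalizationParams()
    if ct_params.fitted_bounds is None:
        ct_params = NormalizationParams(
            ct_clip=ct_params.ct_clip,
            mri_quantiles=ct_params.mri_quantiles,
            stretch_range=ct_params.stretch_range,
            fitted_bounds=ct_params.ct_clip,
            mri_exclude_background=ct_params.mri_exclude_background,
        )
    out = denormalize(reassembled, ct_params)
    return ImageVolume(out.data, mri.spacing, mri.origin, Modality.PSEUDO_CT)
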