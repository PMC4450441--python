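"""Multi-channel confocal z-stack container and TIFF I/O.

An :class:`ImageStack` holds an aligned multi-channel voxel grid together with
its physical calibration (pixels per micrometre in-plane, z-step between
optical sections).  Plane index 0 is the first-acquired (top) focal plane;
stacks are acquired top to bottom, so plane index is also acquisition order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.registration import phase_cross_correlation
import scipy.ndimage as ndi

#: default in-plane calibration: 2048 px across a 510 um field of view
DEFAULT_PX_PER_UM = 2048.0 / 510.0


@dataclass
class ImageStack:
    """Aligned multi-channel 3D voxel grid with physical calibration.

    Parameters
    ----------
    data:
        Array of shape ``(n_planes, n_channels, height, width)`` holding
        fluorescence intensities in arbitrary units (float32).
    channels:
        Channel names, e.g. ``["wall", "reporter_1"]``.  The wall channel
        carries the cell-wall stain; reporter channels carry nuclear
        fluorescence.
    px_per_um:
        In-plane calibration (pixels per micrometre).
    z_step_um:
        Spacing between consecutive optical sections, in micrometres.
    """

    data: np.ndarray
    channels: list[str] = field(default_factory=lambda: ["wall", "reporter_1"])
    px_per_um: float = DEFAULT_PX_PER_UM
    z_step_um: float = 3.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError("stack data must have shape (planes, channels, H, W)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[1]} channel planes but {len(self.channels)} names"
            )
        if self.z_step_um <= 0 or self.px_per_um <= 0:
            raise ValueError("calibration values must be positive")

    # ------------------------------------------------------------------
    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def reporter_channels(self) -> list[str]:
        return [c for c in self.channels if c != "wall"]

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(n_planes, H, W)`` volume for one named channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channels}") from None
        return self.data[:, idx]

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the stack as a multi-page TIFF plus a JSON calibration sidecar.

        Pages are ordered plane-major, channel-minor (one page per
        (plane, channel) pair, axes ZCYX).
        """
        path = Path(path)
        tifffile.imwrite(path, self.data, metadata={"axes": "ZCYX"})
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "channels": self.channels,
                    "px_per_um": self.px_per_um,
                    "z_step_um": self.z_step_um,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        data = tifffile.imread(path)
        if data.ndim == 3:  # single-channel stack
            data = data[:, None]
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        else:
            meta = {
                "channels": [f"ch{i}" for i in range(data.shape[1])],
                "px_per_um": DEFAULT_PX_PER_UM,
                "z_step_um": 3.0,
            }
        return cls(
            data=data,
            channels=list(meta["channels"]),
            px_per_um=float(meta["px_per_um"]),
            z_step_um=float(meta["z_step_um"]),
        )


def align_stack(
    stack: ImageStack,
    reference_channel: str = "wall",
    max_shift_px: float = 30.0,
) -> tuple[ImageStack, np.ndarray]:
    """Register planes by translation (phase correlation on the wall channel).

    Each plane is registered against the previous one and the cumulative
    integer shift is applied to every channel, so all channels stay in
    register with each other.  Stage drift between consecutive optical
    sections is small, so per-pair estimates beyond ``max_shift_px`` are
    treated as unreliable (content change between sections, not drift) and
    replaced by zero.  Returns the aligned stack and the applied per-plane
    ``(row, col)`` shifts.
    """
    ref = stack.channel(reference_channel)
    n = stack.n_planes
    shifts = np.zeros((n, 2))
    if n >= 2:
        cum = np.zeros(2)
        for p in range(1, n):
            step, _, _ = phase_cross_correlation(ref[p - 1], ref[p], normalization=None)
            if np.hypot(*step) > max_shift_px:
                step = np.zeros(2)
            cum = cum + step
            shifts[p] = cum
    shifts = np.round(shifts)
    out = stack.data.copy()
    for p in range(n):
        if np.any(shifts[p]):
            for c in range(out.shape[1]):
                out[p, c] = ndi.shift(stack.data[p, c], shifts[p], order=0, cval=0.0)
    aligned = ImageStack(
        data=out,
        channels=list(stack.channels),
        px_per_um=stack.px_per_um,
        z_step_um=stack.z_step_um,
    )
    return aligned, shifts
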