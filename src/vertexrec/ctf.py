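"""Weak-phase contrast transfer function model.

CTF(f) = -sqrt(1 - A^2) sin(chi) - A cos(chi), with phase aberration
chi(f) = pi * lambda * dz(theta) * f^2 - (pi/2) * Cs * lambda^3 * f^4.
Positive defocus means underfocus; astigmatism makes the effective defocus
direction dependent, dz(theta) = (du + dv)/2 + (du - dv)/2 * cos 2(theta - a).
No envelope function is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom for a voltage in kV."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


@dataclass(frozen=True)
class CTFParams:
    """Microscope/defocus parameters of one particle image."""

    voltage: float = 300.0        # kV
    defocus_u: float = 15000.0    # Angstrom, underfocus positive
    defocus_v: float = 15000.0    # Angstrom
    astig_angle: float = 0.0      # degrees
    cs: float = 2.0               # mm
    amplitude_contrast: float = 0.1

    def __post_init__(self) -> None:
        if self.voltage <= 0:
            raise ValueError("voltage must be positive")
        if self.defocus_u <= 0 or self.defocus_v <= 0:
            raise ValueError("defocus values must be positive (underfocus)")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude contrast must lie in [0, 1]")


def ctf_2d(params: CTFParams, shape: tuple[int, int], pixel_size: float,
           ) -> np.ndarray:
    """Evaluate the CTF on the (unshifted) 2D FFT frequency grid of ``shape``."""
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pixel_size)[:, None]
    fx = np.fft.fftfreq(nx, d=pixel_size)[None, :]
    f2 = fx * fx + fy * fy
    theta = np.arctan2(fy, fx)
    lam = electron_wavelength(params.voltage)
    dz = (0.5 * (params.defocus_u + params.defocus_v)
          + 0.5 * (params.defocus_u - params.defocus_v)
          * np.cos(2.0 * (theta - np.radians(params.astig_angle))))
    cs_ang = params.cs * 1e7  # mm -> Angstrom
    chi = np.pi * lam * dz * f2 - 0.5 * np.pi * cs_ang * lam ** 3 * f2 * f2
    a = params.amplitude_contrast
    return -np.sqrt(1.0 - a * a) * np.sin(chi) - a * np.cos(chi)


def apply_ctf(image: np.ndarray, params: CTFParams, pixel_size: float,
              ) -> np.ndarray:
    """Multiply an image by the CTF in Fourier space (real output)."""
    c = ctf_2d(params, image.shape, pixel_size)
    return np.fft.ifft2(np.fft.fft2(image) * c).real
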