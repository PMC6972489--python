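"""Acquisition protocols for the two supported ASL sequence flavours."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C

# Q2TIPS bolus truncation: below this TI the bolus is TI minus the
# saturation-module gap; above it the bolus is capped at Q2TIPS_TAU_S.
Q2TIPS_TI_BREAK_S = 1.0
Q2TIPS_GAP_S = 0.025
Q2TIPS_TAU_S = 0.75


@dataclass
class AcquisitionParams:
    """Sequence timing and labeling parameters for one ASL protocol.

    ``ti_or_pld_s`` holds inversion times (PASL) or post-labeling delays
    (pCASL), strictly increasing, in seconds.
    """

    sequence: str                             # "PASL" | "pCASL"
    ti_or_pld_s: tuple[float, ...]
    te_ms: float
    tr_s: float
    slice_time_ms: float
    n_repeats: int = 8
    label_duration_s: float = 1.4             # pCASL only
    background_suppression: bool = False
    bs_factor: float = 0.3                    # static-signal attenuation
    presaturation: bool = True
    calib_tr_s: float | None = None           # separate long-TR scan
    alpha: float = C.ALPHA_PASL

    def __post_init__(self):
        if self.sequence not in ("PASL", "pCASL"):
            raise ValueError(f"unknown sequence {self.sequence!r}")
        tis = np.asarray(self.ti_or_pld_s, dtype=float)
        if tis.size < 1 or np.any(np.diff(tis) <= 0):
            raise ValueError("ti_or_pld_s must be strictly increasing")
        if self.te_ms <= 0:
            raise ValueError("te_ms must be positive")
        if self.slice_time_ms < 0:
            raise ValueError("slice_time_ms must be non-negative")

    @classmethod
    def pasl_default(cls, n_repeats: int = 8) -> "AcquisitionParams":
        """PICORE-Q2TIPS-like multi-TI PASL: 11 TIs 400-2400 ms, no
        background suppression, presaturation, ascending 2D readout."""
        return cls(sequence="PASL",
                   ti_or_pld_s=tuple(np.round(np.arange(0.4, 2.41, 0.2), 3)),
                   te_ms=19.0, tr_s=2.5, slice_time_ms=50.0,
                   n_repeats=n_repeats, background_suppression=False,
                   presaturation=True, alpha=C.ALPHA_PASL)

    @classmethod
    def pcasl_default(cls, n_repeats: int = 8) -> "AcquisitionParams":
        """Multi-PLD pCASL: 6 PLDs 250-1500 ms, 1400 ms label,
        background-suppressed, with a separate TR=6 s calibration scan."""
        return cls(sequence="pCASL",
                   ti_or_pld_s=tuple(np.round(np.arange(0.25, 1.51, 0.25), 3)),
                   te_ms=13.0, tr_s=4.0, slice_time_ms=45.2,
                   n_repeats=n_repeats, label_duration_s=1.4,
                   background_suppression=True, presaturation=False,
                   calib_tr_s=6.0, alpha=C.ALPHA_PCASL)

    def bolus_duration(self, ti_or_pld: float) -> float:
        """Bolus duration in seconds for one nominal TI/PLD.

        For Q2TIPS PASL the bolus is truncated: TI - 25 ms below 1 s,
        750 ms otherwise. For pCASL it is the labeling duration.
        """
        if self.sequence == "pCASL":
            return self.label_duration_s
        if ti_or_pld < Q2TIPS_TI_BREAK_S:
            return ti_or_pld - Q2TIPS_GAP_S
        return Q2TIPS_TAU_S

    def bolus_durations(self) -> np.ndarray:
        return np.array([self.bolus_duration(t) for t in self.ti_or_pld_s])

    def model_times(self) -> np.ndarray:
        """Nominal kinetic-model times: TI for PASL, label duration + PLD
        for pCASL (time since the start of labeling)."""
        tis = np.asarray(self.ti_or_pld_s, dtype=float)
        if self.sequence == "pCASL":
            return self.label_duration_s + tis
        return tis

    def effective_times(self, n_slices: int) -> np.ndarray:
        """(n_times, n_slices) model times including the per-slice readout
        offset of an ascending 2D multi-slice acquisition."""
        base = self.model_times()[:, None]
        offsets = np.arange(n_slices)[None, :] * self.slice_time_ms / 1000.0
        return base + offsets
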