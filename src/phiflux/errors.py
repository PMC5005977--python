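"""Exception hierarchy for phiflux."""


class PhifluxError(Exception):
    """Base class for all phiflux errors."""


class ProtocolError(PhifluxError):
    """Invalid superfusion protocol (non-contiguous, overlapping, or malformed phases)."""


class PhysiologyError(PhifluxError):
    """Simulated state left the physical validity of the model (e.g. buffer capacity <= 0)."""


class CalibrationError(PhifluxError):
    """Calibration points or fitted curve violate the ratio-pH mapping contract."""


class RescaleError(CalibrationError):
    """One-point rescale impossible (predicted ratio is zero at the anchor pH)."""


class WindowError(PhifluxError):
    """Analysis window crosses a phase boundary or holds too few samples."""


class QCError(PhifluxError):
    """Trace failed quality control (too many invalid ratio samples)."""


class GeometryError(PhifluxError):
    """ROI geometry invalid (outside field or overlapping)."""


class GateError(PhifluxError):
    """Flow-cytometry gate refers to a channel absent from the event table."""


class SplitError(PhifluxError):
    """Too few cells for a bimodal split."""
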