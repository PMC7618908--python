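"""Shared subject-level data record."""

from __future__ import annotations

from dataclasses import dataclass, field

from asymsurf.mesh_core import AnatomicalSurface, MetricMap

__all__ = ["SubjectRecord"]


@dataclass
class SubjectRecord:
    """One subject's hemispheric data.

    ``metrics`` is nested feature -> hemisphere -> MetricMap; right-hemisphere
    maps are stored already mirrored onto the left topology, so maps of the
    two hemispheres are vertex-wise comparable.  ``surfaces`` is nested
    hemisphere -> role (white/pial/midthickness) -> AnatomicalSurface, each
    hemisphere in its own (unmirrored) frame.
    """

    subject_id: str
    age_weeks: float
    covariates: dict = field(default_factory=dict)
    metrics: dict[str, dict[str, MetricMap]] = field(default_factory=dict)
    surfaces: dict[str, dict[str, AnatomicalSurface]] = field(default_factory=dict)
    timeseries: dict | None = None

    def metric(self, feature: str, hemisphere: str) -> MetricMap:
        try:
            return self.metrics[feature][hemisphere]
        except KeyError as err:
            raise KeyError(
                f"subject {self.subject_id} has no {hemisphere} '{feature}' map"
            ) from err
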