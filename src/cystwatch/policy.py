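"""Decision-policy tables: thresholds and surveillance intervals as data.

The guideline interval schedule is deliberately externalized into a YAML
file rather than hard-coded, so the encoding can be audited and corrected
against the guideline text without touching the engine. Every loaded policy
carries a content checksum that the engine stamps into each recommendation's
rationale trace.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field, PrivateAttr, model_validator

from .models import Modality


class SizeBand(BaseModel):
    """Surveillance rule for cysts in [lower_mm, upper_mm) without WF/HRS.

    ``initial_intervals_months`` are the first visit spacings after entering
    the band; once exhausted the ``stable_interval_months`` applies.
    """

    lower_mm: float = Field(ge=0)
    upper_mm: float = Field(gt=0)
    modality: Modality = Modality.MRI_MRCP
    initial_intervals_months: list[float] = Field(min_length=1)
    stable_interval_months: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "SizeBand":
        if self.upper_mm <= self.lower_mm:
            raise ValueError("size band upper bound must exceed lower bound")
        if any(i <= 0 for i in self.initial_intervals_months):
            raise ValueError("intervals must be positive")
        return self

    def interval_at(self, visit_number: int) -> float:
        """Interval to the next visit, given ``visit_number`` visits already
        completed in this band (0 = recommendation at band entry)."""
        if visit_number < len(self.initial_intervals_months):
            return self.initial_intervals_months[visit_number]
        return self.stable_interval_months


class SurveillanceRule(BaseModel):
    modality: Modality
    interval_months: float = Field(gt=0)


class WfTier(BaseModel):
    """EUS-based rule applied when the cumulative worrisome-feature count
    reaches ``min_count``; the highest applicable tier wins."""

    min_count: int = Field(ge=1)
    modality: Modality = Modality.EUS
    interval_months: float = Field(gt=0)


class Thresholds(BaseModel):
    """Numeric cutoffs for high-risk stigmata and worrisome features (mm,
    U/mL, mm per 2 years). Inclusivity follows the guideline text: duct
    >= 10 mm and enhancing nodule >= 5 mm are stigmata; cyst >= 30 mm and
    duct 5-9 mm (closed) are worrisome; growth is strictly > 5 mm/2 years."""

    mpd_hrs_mm: float = 10.0
    mpd_wf_lower_mm: float = 5.0
    enhancing_nodule_hrs_mm: float = 5.0
    cyst_wf_mm: float = 30.0
    growth_wf_mm_per_2y: float = 5.0
    ca19_9_uln: float = 37.0


class DecisionPolicy(BaseModel):
    name: str = "policy"
    version: str = "0"
    thresholds: Thresholds = Field(default_factory=Thresholds)
    size_bands: list[SizeBand]
    wf_tiers: list[WfTier]
    hrs_rule: str = "surgery_referral"
    unfit_rule: SurveillanceRule
    include_kyoto_wfs: bool = True  # acute pancreatitis / new-onset diabetes
    use_regression_growth: bool = False
    _checksum: Optional[str] = PrivateAttr(default=None)

    @model_validator(mode="after")
    def _validate_bands(self) -> "DecisionPolicy":
        bands = sorted(self.size_bands, key=lambda b: b.lower_mm)
        for a, b in zip(bands, bands[1:]):
            if b.lower_mm < a.upper_mm:
                raise ValueError(
                    f"size bands overlap: ({a.lower_mm},{a.upper_mm}) and ({b.lower_mm},{b.upper_mm})"
                )
        lo = min(b.lower_mm for b in bands)
        hi = max(b.upper_mm for b in bands)
        covered = sum(b.upper_mm - b.lower_mm for b in bands)
        if lo > 0 or hi < self.thresholds.cyst_wf_mm or covered < hi - lo:
            raise ValueError(
                "size bands must partition (0, cyst WF threshold) without gaps"
            )
        if not self.wf_tiers or min(t.min_count for t in self.wf_tiers) != 1:
            raise ValueError("wf_tiers must include a tier with min_count 1")
        return self

    def band_for(self, size_mm: float) -> SizeBand:
        for band in sorted(self.size_bands, key=lambda b: b.lower_mm):
            if band.lower_mm <= size_mm < band.upper_mm:
                return band
        # at/above the top bound the cyst-size WF applies instead; fall back
        # to the widest-interval top band for degenerate calls
        return max(self.size_bands, key=lambda b: b.upper_mm)

    def wf_tier_for(self, wf_count: int) -> WfTier:
        eligible = [t for t in self.wf_tiers if t.min_count <= wf_count]
        return max(eligible, key=lambda t: t.min_count)

    def checksum(self) -> str:
        if self._checksum is None:
            payload = self.model_dump_json(exclude_none=True)
            self._checksum = hashlib.sha256(payload.encode()).hexdigest()[:12]
        return self._checksum


def load_policy(path: Optional[Union[str, Path]] = None) -> DecisionPolicy:
    """Load a policy YAML file; with no argument, the shipped default
    encoding of the Kyoto decision tree."""
    if path is None:
        text = resources.files("cystwatch.data").joinpath("kyoto_policy.yaml").read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    return DecisionPolicy.model_validate(data)


def default_policy() -> DecisionPolicy:
    return load_policy(None)
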