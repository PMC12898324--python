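# Default decision policy: Kyoto (2024) surveillance tree for SB-IPMN.
# Thresholds in mm (CA 19-9 in U/mL); intervals in months.
#
# High-risk stigmata (any one -> surgical referral for fit patients):
#   main pancreatic duct >= 10 mm, obstructive jaundice,
#   enhancing mural nodule >= 5 mm.
# Worrisome features (any -> EUS-based surveillance; count is cumulative):
#   cyst >= 30 mm, small/non-enhancing mural nodule, thickened wall,
#   duct 5-9 mm, abrupt duct calibre change, lymphadenopathy,
#   CA 19-9 > 37 U/mL, growth > 5 mm per 2 years, plus the Kyoto additions
#   (acute pancreatitis episode, new-onset diabetes).
name: kyoto-2024-default
version: "1"
thresholds:
  mpd_hrs_mm: 10.0
  mpd_wf_lower_mm: 5.0
  enhancing_nodule_hrs_mm: 5.0
  cyst_wf_mm: 30.0
  growth_wf_mm_per_2y: 5.0
  ca19_9_uln: 37.0
size_bands:
  # < 20 mm, no WF/HRS: MRI/MRCP at 6 months, then every 18 months if stable
  - lower_mm: 0
    upper_mm: 20
    modality: mri_mrcp
    initial_intervals_months: [6]
    stable_interval_months: 18
  # 20-29 mm: every 6 months for the first year, then every 12 months
  - lower_mm: 20
    upper_mm: 30
    modality: mri_mrcp
    initial_intervals_months: [6, 6]
    stable_interval_months: 12
wf_tiers:
  # any worrisome feature: EUS work-up then imaging every 6 months;
  # add tiers with larger min_count to escalate with the cumulative WF count
  - min_count: 1
    modality: eus
    interval_months: 6
hrs_rule: surgery_referral
# stigmata present but patient not surgically fit: EUS every 6 months
unfit_rule:
  modality: eus
  interval_months: 6
include_kyoto_wfs: true
use_regression_growth: false
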