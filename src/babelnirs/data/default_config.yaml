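# Default pipeline configuration: 46-channel infant montage,
# frontotemporal ROIs, four-condition two-modality design.
# Anatomical labels are placeholders (the montage's channel->anatomy
# lookup is given only through ROI membership).
montage:
  source_detector_separation_cm: 2.0
  wavelengths_nm:
  - 770.0
  - 850.0
  sampling_rate_hz: 10.0
  channels:
  - channel_id: 1
    source_id: S1
    detector_id: D1
    hemisphere: left
    label: left frontal
  - channel_id: 2
    source_id: S1
    detector_id: D2
    hemisphere: left
    label: left frontal
  - channel_id: 3
    source_id: S2
    detector_id: D1
    hemisphere: left
    label: left frontal
  - channel_id: 4
    source_id: S2
    detector_id: D2
    hemisphere: left
    label: left frontal
  - channel_id: 5
    source_id: S2
    detector_id: D3
    hemisphere: left
    label: left frontal
  - channel_id: 6
    source_id: S3
    detector_id: D2
    hemisphere: left
    label: left frontal
  - channel_id: 7
    source_id: S3
    detector_id: D3
    hemisphere: left
    label: left frontal
  - channel_id: 8
    source_id: S3
    detector_id: D4
    hemisphere: left
    label: left frontal
  - channel_id: 9
    source_id: S4
    detector_id: D3
    hemisphere: left
    label: left temporal
  - channel_id: 10
    source_id: S4
    detector_id: D4
    hemisphere: left
    label: left temporal
  - channel_id: 11
    source_id: S4
    detector_id: D5
    hemisphere: left
    label: left temporal
  - channel_id: 12
    source_id: S5
    detector_id: D4
    hemisphere: left
    label: left temporal
  - channel_id: 13
    source_id: S5
    detector_id: D5
    hemisphere: left
    label: left temporal
  - channel_id: 14
    source_id: S5
    detector_id: D6
    hemisphere: left
    label: left temporal
  - channel_id: 15
    source_id: S6
    detector_id: D5
    hemisphere: left
    label: left temporal
  - channel_id: 16
    source_id: S6
    detector_id: D6
    hemisphere: left
    label: left temporal
  - channel_id: 17
    source_id: S6
    detector_id: D7
    hemisphere: left
    label: left temporoparietal
  - channel_id: 18
    source_id: S7
    detector_id: D6
    hemisphere: left
    label: left temporoparietal
  - channel_id: 19
    source_id: S7
    detector_id: D7
    hemisphere: left
    label: left temporoparietal
  - channel_id: 20
    source_id: S7
    detector_id: D8
    hemisphere: left
    label: left temporoparietal
  - channel_id: 21
    source_id: S8
    detector_id: D7
    hemisphere: left
    label: left temporoparietal
  - channel_id: 22
    source_id: S8
    detector_id: D8
    hemisphere: left
    label: left temporoparietal
  - channel_id: 23
    source_id: S1
    detector_id: D3
    hemisphere: left
    label: left temporoparietal
  - channel_id: 24
    source_id: S9
    detector_id: D9
    hemisphere: right
    label: right frontal
  - channel_id: 25
    source_id: S9
    detector_id: D10
    hemisphere: right
    label: right frontal
  - channel_id: 26
    source_id: S10
    detector_id: D9
    hemisphere: right
    label: right frontal
  - channel_id: 27
    source_id: S10
    detector_id: D10
    hemisphere: right
    label: right frontal
  - channel_id: 28
    source_id: S10
    detector_id: D11
    hemisphere: right
    label: right frontal
  - channel_id: 29
    source_id: S11
    detector_id: D10
    hemisphere: right
    label: right frontal
  - channel_id: 30
    source_id: S11
    detector_id: D11
    hemisphere: right
    label: right frontal
  - channel_id: 31
    source_id: S11
    detector_id: D12
    hemisphere: right
    label: right frontal
  - channel_id: 32
    source_id: S12
    detector_id: D11
    hemisphere: right
    label: right temporal
  - channel_id: 33
    source_id: S12
    detector_id: D12
    hemisphere: right
    label: right temporal
  - channel_id: 34
    source_id: S12
    detector_id: D13
    hemisphere: right
    label: right temporal
  - channel_id: 35
    source_id: S13
    detector_id: D12
    hemisphere: right
    label: right temporal
  - channel_id: 36
    source_id: S13
    detector_id: D13
    hemisphere: right
    label: right temporal
  - channel_id: 37
    source_id: S13
    detector_id: D14
    hemisphere: right
    label: right temporal
  - channel_id: 38
    source_id: S14
    detector_id: D13
    hemisphere: right
    label: right temporal
  - channel_id: 39
    source_id: S14
    detector_id: D14
    hemisphere: right
    label: right temporal
  - channel_id: 40
    source_id: S14
    detector_id: D15
    hemisphere: right
    label: right temporoparietal
  - channel_id: 41
    source_id: S15
    detector_id: D14
    hemisphere: right
    label: right temporoparietal
  - channel_id: 42
    source_id: S15
    detector_id: D15
    hemisphere: right
    label: right temporoparietal
  - channel_id: 43
    source_id: S15
    detector_id: D16
    hemisphere: right
    label: right temporoparietal
  - channel_id: 44
    source_id: S16
    detector_id: D15
    hemisphere: right
    label: right temporoparietal
  - channel_id: 45
    source_id: S16
    detector_id: D16
    hemisphere: right
    label: right temporoparietal
  - channel_id: 46
    source_id: S9
    detector_id: D11
    hemisphere: right
    label: right temporoparietal
rois:
  inferior_frontal:
  - 2
  - 3
  - 5
  - 6
  - 25
  - 26
  - 28
  - 29
  posterior_temporal:
  - 17
  - 19
  - 20
  - 22
  - 40
  - 42
  - 43
  - 45
design:
  conditions:
  - English
  - French
  - BSL
  - LSFB
  modality_map:
    English: spoken
    French: spoken
    BSL: signed
    LSFB: signed
  familiarity_map:
    monolingual:
      English: familiar
      French: unfamiliar
      BSL: n/a
      LSFB: n/a
    unimodal_bilingual:
      English: familiar
      French: unfamiliar
      BSL: n/a
      LSFB: n/a
    bimodal_bilingual:
      English: familiar
      French: unfamiliar
      BSL: familiar
      LSFB: unfamiliar
  baseline_duration_s: 10.0
  stimulus_duration_range_s:
  - 9.0
  - 12.0
  max_experimental_trials: 20
qc:
  cov_threshold_percent: 15.0
  normalized_power_threshold: 0.5
  npp_min_frequency_hz: 0.5
  max_rejected_channels: 15
  cov_domain: intensity
  drift_screening_enabled: false
  drift_threshold: null
preprocess:
  lowpass_cutoff_hz: 1.7
  filter_order: 4
  epoch_window_s:
  - -4.0
  - 20.0
  baseline_reject_threshold_umol: 3.0
  stimulus_reject_threshold_umol: 5.0
  stimulus_window_s:
  - 0.0
  - 10.0
  looking_threshold: 0.6
  min_valid_trials: 3
  trial_validity_rule: 0.5
  dpf: 5.13
  extinction:
    770.0:
      hbo2: 0.65
      hhb: 1.3029
    850.0:
      hbo2: 1.058
      hhb: 0.6915
analysis:
  peak_window_s:
  - 8.0
  - 16.0
  n_channels_fdr: 46
  svm_c: 1.0
  n_permutations: 1000
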