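# Default acceleration archetypes for the synthetic running cohort.
#
# Group sizes, vertical excursions, peak joint angles and demographics follow
# the published cohort summary this generator emulates; acceleration peak
# amplitudes (in g) and timings (cycle/stance fractions) are free generator
# parameters chosen to reproduce the qualitative between-group contrasts
# (C2: higher vertical peak, greater and delayed anterior peak, delayed
# medio-lateral peak, lower early-stance magnitude; C1: lowest vertical
# excursion; females: higher, later medio-lateral peaks than males).
male:
  sex: male
  n_subjects: 44
  cadence_spm: 168.0
  cadence_sd_spm: 4.0
  stance_fraction: 0.65
  vertical_excursion_mm: 104.7
  vertical_excursion_sd_mm: 2.1
  vt_peak_g: 2.55
  vt_peak_phase: 0.20
  vt_impact_g: 1.50
  vt_impact_phase: 0.05
  ap_peak_g: 0.90
  ap_peak_phase: 0.52
  ml_peak_g: 0.22
  ml_peak_phase: 0.16
  amp_cv: 0.05
  phase_jitter: 0.010
  marker_noise_mm: 0.5
  demographic_means: {age: 35.1, height: 1.79, mass: 77.2, running_speed: 2.66, years_running: 8.6}
  demographic_sds: {age: 1.5, height: 0.01, mass: 1.3, running_speed: 0.03, years_running: 8.0}
  p_unilateral: 0.4545   # 20 / 44
  p_single_site: 0.75    # 33 / 44
  peak_angle_means: {ankle_eversion: 7.2, knee_flexion: 44.6, knee_abduction: 9.3,
                     knee_external_rotation: 10.0, hip_adduction: 8.2, hip_internal_rotation: 12.7}
  peak_angle_sds: {ankle_eversion: 0.6, knee_flexion: 0.9, knee_abduction: 0.7,
                   knee_external_rotation: 1.4, hip_adduction: 0.7, hip_internal_rotation: 1.1}

female_C1:
  sex: female
  n_subjects: 26
  cadence_spm: 172.0
  cadence_sd_spm: 4.0
  stance_fraction: 0.65
  vertical_excursion_mm: 88.8
  vertical_excursion_sd_mm: 2.7
  vt_peak_g: 2.70
  vt_peak_phase: 0.20
  vt_impact_g: 1.40
  vt_impact_phase: 0.05
  ap_peak_g: 1.00
  ap_peak_phase: 0.55
  ml_peak_g: 0.85
  ml_peak_phase: 0.38
  amp_cv: 0.05
  phase_jitter: 0.010
  marker_noise_mm: 0.5
  demographic_means: {age: 30.9, height: 1.66, mass: 59.1, running_speed: 2.60, years_running: 7.0}
  demographic_sds: {age: 2.0, height: 0.01, mass: 1.7, running_speed: 0.04, years_running: 7.1}
  p_unilateral: 0.5      # 13 / 26
  p_single_site: 0.7308  # 19 / 26
  peak_angle_means: {ankle_eversion: 4.1, knee_flexion: 43.2, knee_abduction: 11.9,
                     knee_external_rotation: 11.1, hip_adduction: 10.9, hip_internal_rotation: 18.3}
  peak_angle_sds: {ankle_eversion: 0.8, knee_flexion: 1.2, knee_abduction: 0.9,
                   knee_external_rotation: 1.8, hip_adduction: 0.9, hip_internal_rotation: 1.4}

female_C2:
  sex: female
  n_subjects: 40
  cadence_spm: 170.0
  cadence_sd_spm: 4.0
  stance_fraction: 0.65
  vertical_excursion_mm: 98.9
  vertical_excursion_sd_mm: 2.2
  vt_peak_g: 3.10
  vt_peak_phase: 0.22
  vt_impact_g: 1.30
  vt_impact_phase: 0.05
  ap_peak_g: 1.25
  ap_peak_phase: 0.66
  ml_peak_g: 0.95
  ml_peak_phase: 0.48
  amp_cv: 0.05
  phase_jitter: 0.010
  marker_noise_mm: 0.5
  demographic_means: {age: 36.4, height: 1.66, mass: 63.4, running_speed: 2.57, years_running: 9.0}
  demographic_sds: {age: 1.6, height: 0.01, mass: 1.4, running_speed: 0.03, years_running: 7.7}
  p_unilateral: 0.35     # 14 / 40
  p_single_site: 0.8     # 32 / 40
  peak_angle_means: {ankle_eversion: 4.2, knee_flexion: 44.2, knee_abduction: 12.4,
                     knee_external_rotation: 7.6, hip_adduction: 11.6, hip_internal_rotation: 15.8}
  peak_angle_sds: {ankle_eversion: 0.7, knee_flexion: 0.9, knee_abduction: 0.7,
                   knee_external_rotation: 1.4, hip_adduction: 0.7, hip_internal_rotation: 1.1}
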