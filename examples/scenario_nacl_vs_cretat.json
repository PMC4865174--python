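{
  "cohorts": {
    "Cre-TAT": {
      "bin_factor": 1,
      "eps_scale": 1.0,
      "ground_truth": {
        "baseline_reflectance": 1.0,
        "eyes": {
          "contra": {
            "acuity_cpd": 0.5,
            "peak_sf_cpd": 0.0303,
            "response_amplitude": 0.002
          },
          "ipsi": {
            "acuity_cpd": 0.5,
            "peak_sf_cpd": 0.0303,
            "response_amplitude": 0.0018
          }
        },
        "frame_duration_s": 1.0,
        "hemodynamic_weights": [
          0.0,
          0.5,
          1.0,
          1.0,
          1.0
        ],
        "illumination_wavelength_nm": 700.0,
        "image_shape": [
          32,
          32
        ],
        "noise": {
          "drift_rho": 0.98,
          "drift_sd": 0.002,
          "vascular_corr_px": 3.0,
          "vascular_sd": 0.0005,
          "white_sd": 0.002
        },
        "pixel_size_um": 84.0,
        "roi": {
          "axes_yx": [
            7.0,
            5.0
          ],
          "center_yx": [
            16.0,
            17.0
          ],
          "taper_px": 2.0
        },
        "seed": 0
      },
      "input_dir": null,
      "integration_domain": "log10",
      "manual_roi_path": null,
      "n_null_permutations": 3,
      "n_response_frames": 3,
      "n_roi_sfs": 3,
      "noise_floor": 0.05,
      "output_dir": null,
      "protocol": {
        "eyes": [
          "contra",
          "ipsi"
        ],
        "interstimulus_gray_s": 10.0,
        "n_orientations": 16,
        "n_repeats": 16,
        "sf_values_cpd": [
          0.0303,
          0.04468597367493438,
          0.06590218624676336,
          0.09719153002453763,
          0.1433365726766694,
          0.21139057139554351,
          0.3117555613369835,
          0.4597723038587075,
          0.6780651177126777,
          1.0
        ],
        "stimulus_duration_s": 5.0,
        "temporal_frequency_hz": 1.5
      },
      "retain_rule": "permutation",
      "retain_threshold": 1.0,
      "roi_eye": "ipsi",
      "roi_z_threshold": 2.0,
      "seed": 0,
      "smooth_sd_px": 3.0,
      "use_gif": true
    },
    "NaCl": {
      "bin_factor": 1,
      "eps_scale": 1.0,
      "ground_truth": {
        "baseline_reflectance": 1.0,
        "eyes": {
          "contra": {
            "acuity_cpd": 0.5,
            "peak_sf_cpd": 0.0303,
            "response_amplitude": 0.002
          },
          "ipsi": {
            "acuity_cpd": 0.35,
            "peak_sf_cpd": 0.0303,
            "response_amplitude": 0.0014
          }
        },
        "frame_duration_s": 1.0,
        "hemodynamic_weights": [
          0.0,
          0.5,
          1.0,
          1.0,
          1.0
        ],
        "illumination_wavelength_nm": 700.0,
        "image_shape": [
          32,
          32
        ],
        "noise": {
          "drift_rho": 0.98,
          "drift_sd": 0.002,
          "vascular_corr_px": 3.0,
          "vascular_sd": 0.0005,
          "white_sd": 0.002
        },
        "pixel_size_um": 84.0,
        "roi": {
          "axes_yx": [
            7.0,
            5.0
          ],
          "center_yx": [
            16.0,
            17.0
          ],
          "taper_px": 2.0
        },
        "seed": 0
      },
      "input_dir": null,
      "integration_domain": "log10",
      "manual_roi_path": null,
      "n_null_permutations": 3,
      "n_response_frames": 3,
      "n_roi_sfs": 3,
      "noise_floor": 0.05,
      "output_dir": null,
      "protocol": {
        "eyes": [
          "contra",
          "ipsi"
        ],
        "interstimulus_gray_s": 10.0,
        "n_orientations": 16,
        "n_repeats": 16,
        "sf_values_cpd": [
          0.0303,
          0.04468597367493438,
          0.06590218624676336,
          0.09719153002453763,
          0.1433365726766694,
          0.21139057139554351,
          0.3117555613369835,
          0.4597723038587075,
          0.6780651177126777,
          1.0
        ],
        "stimulus_duration_s": 5.0,
        "temporal_frequency_hz": 1.5
      },
      "retain_rule": "permutation",
      "retain_threshold": 1.0,
      "roi_eye": "ipsi",
      "roi_z_threshold": 2.0,
      "seed": 0,
      "smooth_sd_px": 3.0,
      "use_gif": true
    }
  },
  "compare_eye": "ipsi",
  "description": "Two simulated cohorts for an end-to-end demonstration: the treated cohort differs from control only in ipsilateral-eye acuity and response amplitude, so the contralateral acuity should not differ while the ipsilateral acuity and the high-SF ocular dominance profile should.",
  "n_per_group": 5
}
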