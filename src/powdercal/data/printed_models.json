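{
  "comment": "Published CARS-PLSR calibration equations on LNIR reflectance (coefficients kept as decimal strings; one-decimal printed precision is authoritative) and the published CARS-selected wavelength sets per adulterant and band.",
  "models": {
    "A": {
      "intercept": "135.7",
      "terms": [
        ["937", "29.3"],
        ["984", "-24.1"],
        ["1508", "-11.5"],
        ["1951", "13.8"],
        ["2003", "-10.5"],
        ["2407", "4.1"]
      ]
    },
    "B": {
      "intercept": "96.9",
      "terms": [
        ["1580", "-8.3"],
        ["1886", "3.2"],
        ["1945", "16.2"],
        ["2311", "-13.4"]
      ]
    },
    "C": {
      "intercept": "9.5",
      "terms": [
        ["944", "-13.0"],
        ["1004", "5.1"],
        ["1018", "7.6"],
        ["1606", "-9.3"],
        ["1912", "17.1"],
        ["2048", "-7.4"],
        ["2496", "-6.1"],
        ["2502", "4.7"]
      ]
    }
  },
  "selected_wavelengths_nm": {
    "A": {
      "VIS": [406, 408, 431, 439, 475, 476, 537, 697],
      "SNIR": [755, 926, 1016],
      "LNIR": [937, 984, 1508, 1951, 2003, 2407]
    },
    "B": {
      "VIS": [506, 508, 509, 511, 541, 578, 579, 621, 629, 634, 699],
      "SNIR": [700, 750, 865, 980, 992, 1040],
      "LNIR": [1580, 1886, 1945, 2311]
    },
    "C": {
      "VIS": [361, 393, 699, 700],
      "SNIR": [737, 745, 858, 941],
      "LNIR": [944, 1004, 1018, 1606, 1912, 2048, 2496, 2502]
    }
  }
}
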