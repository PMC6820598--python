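{
  "name": "pdFVIII-VWF concentrate, routine clinical care development",
  "version": "1",
  "fixed": {
    "CL": 0.195,
    "V1": 2.3,
    "Q": 0.078,
    "V2": 0.449
  },
  "effects": [
    {
      "parameter": "CL",
      "covariate": "FFM",
      "form": "power",
      "theta": 0.701,
      "median": 50.5
    },
    {
      "parameter": "V1",
      "covariate": "FFM",
      "form": "power",
      "theta": 0.726,
      "median": 50.5
    },
    {
      "parameter": "V2",
      "covariate": "FFM",
      "form": "power",
      "theta": 0.842,
      "median": 50.5
    },
    {
      "parameter": "CL",
      "covariate": "age",
      "form": "piecewise_age",
      "theta": -0.302,
      "median": 25.0
    }
  ],
  "omega": [
    [
      0.207936,
      0.19698014400000002
    ],
    [
      0.19698014400000002,
      0.293764
    ]
  ],
  "sigma_prop": 0.205,
  "sigma_add": 0.0
}
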