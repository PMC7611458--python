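{
  "version": "1.0",
  "comment": "First-order line lists for the 20-compound brain basis set. Chemical shifts (ppm, water at 4.65) and scalar couplings (Hz) follow published proton shift/J compilations for brain metabolites; strongly coupled spin systems are approximated as weakly coupled multiplets. j_hz and n_partners may be scalars or parallel lists; splittings are applied sequentially.",
  "metabolites": [
    {
      "metabolite": "Ala",
      "groups": [
        {"ppm": 1.467, "n_protons": 3, "j_hz": 7.2, "n_partners": 1},
        {"ppm": 3.775, "n_protons": 1, "j_hz": 7.2, "n_partners": 3}
      ]
    },
    {
      "metabolite": "Asp",
      "groups": [
        {"ppm": 2.654, "n_protons": 1, "j_hz": [17.4, 9.1], "n_partners": [1, 1]},
        {"ppm": 2.801, "n_protons": 1, "j_hz": [17.4, 3.7], "n_partners": [1, 1]},
        {"ppm": 3.891, "n_protons": 1, "j_hz": [9.1, 3.7], "n_partners": [1, 1]}
      ]
    },
    {
      "metabolite": "Asc",
      "groups": [
        {"ppm": 4.492, "n_protons": 1, "j_hz": 2.0, "n_partners": 1},
        {"ppm": 4.002, "n_protons": 1, "j_hz": [7.0, 2.0], "n_partners": [1, 1]},
        {"ppm": 3.73, "n_protons": 2, "j_hz": 7.0, "n_partners": 1}
      ]
    },
    {
      "metabolite": "GPC",
      "groups": [
        {"ppm": 3.212, "n_protons": 9, "j_hz": 0.0, "n_partners": 0},
        {"ppm": 3.659, "n_protons": 2, "j_hz": 5.8, "n_partners": 2},
        {"ppm": 4.312, "n_protons": 2, "j_hz": 5.8, "n_partners": 2},
        {"ppm": 3.605, "n_protons": 2, "j_hz": 6.0, "n_partners": 1},
        {"ppm": 3.895, "n_protons": 1, "j_hz": 5.8, "n_partners": 2},
        {"ppm": 3.946, "n_protons": 2, "j_hz": 5.8, "n_partners": 1}
      ]
    },
    {
      "metabolite": "PCho",
      "groups": [
        {"ppm": 3.208, "n_protons": 9, "j_hz": 0.0, "n_partners": 0},
        {"ppm": 3.584, "n_protons": 2, "j_hz": 5.9, "n_partners": 2},
        {"ppm": 4.16, "n_protons": 2, "j_hz": 5.9, "n_partners": 2}
      ]
    },
    {
      "metabolite": "Cr",
      "groups": [
        {"ppm": 3.027, "n_protons": 3, "j_hz": 0.0, "n_partners": 0},
        {"ppm": 3.913, "n_protons": 2, "j_hz": 0.0, "n_partners": 0}
      ]
    },
    {
      "metabolite": "PCr",
      "groups": [
        {"ppm": 3.029, "n_protons": 3, "j_hz": 0.0, "n_partners": 0},
        {"ppm": 3.93, "n_protons": 2, "j_hz": 0.0, "n_partners": 0}
      ]
    },
    {
      "metabolite": "GABA",
      "groups": [
        {"ppm": 2.284, "n_protons": 2, "j_hz": 7.3, "n_partners": 2},
        {"ppm": 1.889, "n_protons": 2, "j_hz": 7.3, "n_partners": 4},
        {"ppm": 3.013, "n_protons": 2, "j_hz": 7.3, "n_partners": 2}
      ]
    },
    {
      "metabolite": "Glc",
      "groups": [
        {"ppm": 5.23, "n_protons": 1, "j_hz": 3.8, "n_partners": 1},
        {"ppm": 3.519, "n_protons": 1, "j_hz": 9.1, "n_partners": 2},
        {"ppm": 3.698, "n_protons": 1, "j_hz": 9.4, "n_partners": 2},
        {"ppm": 3.395, "n_protons": 1, "j_hz": 9.4, "n_partners": 2},
        {"ppm": 3.822, "n_protons": 1, "j_hz": 5.8, "n_partners": 2},
        {"ppm": 3.826, "n_protons": 1, "j_hz": 12.1, "n_partners": 1},
        {"ppm": 3.749, "n_protons": 1, "j_hz": 12.1, "n_partners": 1}
      ]
    },
    {
      "metabolite": "Gln",
      "groups": [
        {"ppm": 2.135, "n_protons": 2, "j_hz": 7.0, "n_partners": 3},
        {"ppm": 2.444, "n_protons": 2, "j_hz": 7.2, "n_partners": 2},
        {"ppm": 3.757, "n_protons": 1, "j_hz": 6.1, "n_partners": 2}
      ]
    },
    {
      "metabolite": "Glu",
      "groups": [
        {"ppm": 2.042, "n_protons": 1, "j_hz": [7.3, 7.3], "n_partners": [2, 1]},
        {"ppm": 2.12, "n_protons": 1, "j_hz": [7.3, 7.3], "n_partners": [2, 1]},
        {"ppm": 2.342, "n_protons": 2, "j_hz": 7.5, "n_partners": 2},
        {"ppm": 3.746, "n_protons": 1, "j_hz": 6.5, "n_partners": 2}
      ]
    },
    {
      "metabolite": "GSH",
      "groups": [
        {"ppm": 2.159, "n_protons": 2, "j_hz": 7.1, "n_partners": 3},
        {"ppm": 2.546, "n_protons": 2, "j_hz": 7.3, "n_partners": 2},
        {"ppm": 2.926, "n_protons": 1, "j_hz": [14.1, 7.1], "n_partners": [1, 1]},
        {"ppm": 2.975, "n_protons": 1, "j_hz": [14.1, 4.7], "n_partners": [1, 1]},
        {"ppm": 3.769, "n_protons": 2, "j_hz": 0.0, "n_partners": 0},
        {"ppm": 4.561, "n_protons": 1, "j_hz": 7.1, "n_partners": 2},
        {"ppm": 3.77, "n_protons": 1, "j_hz": 6.3, "n_partners": 2}
      ]
    },
    {
      "metabolite": "Ins",
      "groups": [
        {"ppm": 3.522, "n_protons": 2, "j_hz": [9.9, 2.9], "n_partners": [1, 1]},
        {"ppm": 3.614, "n_protons": 2, "j_hz": 9.5, "n_partners": 2},
        {"ppm": 4.054, "n_protons": 1, "j_hz": 2.9, "n_partners": 2},
        {"ppm": 3.269, "n_protons": 1, "j_hz": 9.3, "n_partners": 2}
      ]
    },
    {
      "metabolite": "Lac",
      "groups": [
        {"ppm": 1.313, "n_protons": 3, "j_hz": 6.9, "n_partners": 1},
        {"ppm": 4.099, "n_protons": 1, "j_hz": 6.9, "n_partners": 3}
      ]
    },
    {
      "metabolite": "NAA",
      "groups": [
        {"ppm": 2.008, "n_protons": 3, "j_hz": 0.0, "n_partners": 0},
        {"ppm": 2.486, "n_protons": 1, "j_hz": [16.6, 9.1], "n_partners": [1, 1]},
        {"ppm": 2.673, "n_protons": 1, "j_hz": [16.6, 3.9], "n_partners": [1, 1]},
        {"ppm": 4.382, "n_protons": 1, "j_hz": [9.1, 3.9], "n_partners": [1, 1]}
      ]
    },
    {
      "metabolite": "NAAG",
      "groups": [
        {"ppm": 2.042, "n_protons": 3, "j_hz": 0.0, "n_partners": 0},
        {"ppm": 2.519, "n_protons": 1, "j_hz": [16.0, 9.0], "n_partners": [1, 1]},
        {"ppm": 2.721, "n_protons": 1, "j_hz": [16.0, 4.0], "n_partners": [1, 1]},
        {"ppm": 4.607, "n_protons": 1, "j_hz": [9.0, 4.0], "n_partners": [1, 1]},
        {"ppm": 2.19, "n_protons": 2, "j_hz": 7.3, "n_partners": 3},
        {"ppm": 2.52, "n_protons": 2, "j_hz": 7.5, "n_partners": 2},
        {"ppm": 4.128, "n_protons": 1, "j_hz": 6.8, "n_partners": 2}
      ]
    },
    {
      "metabolite": "PE",
      "groups": [
        {"ppm": 3.216, "n_protons": 2, "j_hz": 6.6, "n_partners": 2},
        {"ppm": 3.977, "n_protons": 2, "j_hz": 6.6, "n_partners": 2}
      ]
    },
    {
      "metabolite": "sIns",
      "groups": [
        {"ppm": 3.346, "n_protons": 6, "j_hz": 0.0, "n_partners": 0}
      ]
    },
    {
      "metabolite": "Tau",
      "groups": [
        {"ppm": 3.246, "n_protons": 2, "j_hz": 6.6, "n_partners": 2},
        {"ppm": 3.42, "n_protons": 2, "j_hz": 6.6, "n_partners": 2}
      ]
    },
    {
      "metabolite": "water",
      "groups": [
        {"ppm": 4.65, "n_protons": 2, "j_hz": 0.0, "n_partners": 0}
      ]
    }
  ]
}
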