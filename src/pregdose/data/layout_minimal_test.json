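{
  "_comment": "Tiny scene (envelope + 4 organ labels) for fast tests.",
  "grid_hint_mm": [4.0, 4.0, 4.0],
  "fetus_labels": [],
  "envelope": {
    "label": 1, "name": "residual tissue", "region": "remaining tissues",
    "material": "soft_tissue", "source": true, "adjust": false,
    "shape": {"shape": "capsule", "p0": [0, 0, 30], "p1": [0, 0, 130], "radius": 60}
  },
  "organs": [
    {"label": 2, "name": "thyroid", "region": "thyroid", "material": "thyroid",
     "target_mass_g": 17.0, "reference_mass_g": 17.0, "nesting_parent": 1,
     "source": true, "size_from_mass": true,
     "shape": {"shape": "ellipsoid", "center": [0, 25, 150], "semi_axes": [10, 6, 14]}},
    {"label": 3, "name": "stomach contents", "region": "stomach",
     "material": "gi_content", "target_mass_g": 165.84, "reference_mass_g": 230.01,
     "nesting_parent": 1, "source": true, "size_from_mass": true,
     "sizing_mass_g": 305.84,
     "shape": {"shape": "ellipsoid", "center": [0, 0, 70], "semi_axes": [10, 10, 10]},
     "wall": {"n_layers": 1, "label": 4, "name": "stomach wall",
              "material": "soft_tissue", "region": "stomach",
              "target_mass_g": 140.0, "reference_mass_g": 140.0, "source": true}},
    {"label": 5, "name": "liver", "region": "liver", "material": "soft_tissue",
     "target_mass_g": 150.0, "reference_mass_g": 150.0, "nesting_parent": 1,
     "source": true, "size_from_mass": true,
     "shape": {"shape": "ellipsoid", "center": [0, -18, 5], "semi_axes": [46, 32.9, 23]}}
  ]
}
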