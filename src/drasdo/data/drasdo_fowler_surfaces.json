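{
  "description": "Wide-angle schematic eye of the Drasdo-Fowler type: four spherical refracting surfaces (Le Grand-type anterior segment) followed by a spherical retina. Radii are positive when the center of curvature lies behind (posterior to) the vertex. 'n_after' is the refractive index of the medium following the surface. Distances in mm from the corneal vertex.",
  "n_object": 1.0,
  "stop_z_mm": 3.6,
  "surfaces": [
    {"name": "anterior cornea",  "radius_mm": 7.80,  "vertex_z_mm": 0.00, "n_after": 1.3771},
    {"name": "posterior cornea", "radius_mm": 6.50,  "vertex_z_mm": 0.55, "n_after": 1.3374},
    {"name": "anterior lens",    "radius_mm": 10.20, "vertex_z_mm": 3.60, "n_after": 1.4200},
    {"name": "posterior lens",   "radius_mm": -6.00, "vertex_z_mm": 7.60, "n_after": 1.3360}
  ],
  "retina_original": {"radius_mm": 11.06, "center_z_mm": 11.95},
  "retina_rescaled": {"radius_mm": 11.459, "center_z_mm": 12.38},
  "version": 1
}
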