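# Shared study constants (all dimensionless, mm, cm, g/cm3 as named).
dry_matter_fraction: 0.47        # representative solids content of commercial inks
dry_matter_range: [0.31, 0.62]   # surveyed range, used by the random-ink generator
tattoo_z_mm: [1.25, 1.55]        # intradermal pigment sublayer below the skin surface
scoring_depth_mm: 2.4            # depth extent of the dose-scoring mesh
scoring_dz_mm: 0.1               # depth bin width (24 bins over 0-2.4 mm)
scoring_dxy_mm: 2.0              # lateral bin width for uniform-layout runs
scoring_dxy_quadrant_mm: 2.5     # lateral bin width for quadrant-layout runs
field_cm: 1.0                    # square field side at the surface
ssd_cm: 100.0                    # source-to-surface distance
water_backing_mm: 100.0          # backscatter water slab beneath the skin
lateral_extent_mm: 30.0          # full lateral phantom width (3x3 cm)
reticular_dermis_density: 1.1    # mixing partner for tattoo-dermis blends
loadings_vol_percent: [0, 5, 10, 25, 50, 75, 100]
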