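"""Compare 3D biodistribution shapes: compact papule vs needle tracks.

Real intralesional injections produce anything from one compact bolus to
fractured deposits along needle tracks.  This script simulates both
extremes and prints the shape descriptors that tell them apart.
"""

from cryodist import (
    DepotSpec,
    ImagingConfig,
    TissueSpec,
    build_tissue_mask,
    make_phantom,
    quant_report,
    resample_stack_to_volume,
    segment_fluorescence,
    simulate_blockface_stack,
)

tissue = TissueSpec(block_extent=(3600.0, 3600.0, 2400.0), embedding_margin=400.0)
depots = {
    "compact bolus": DepotSpec(
        shape_kind="multilobe",
        center=(2200.0, 2200.0, 1100.0),
        size_params={
            "lobes": [
                {"offset": (0.0, 0.0, 0.0), "radius": 450.0},
                {"offset": (300.0, 150.0, 200.0), "radius": 300.0},
            ]
        },
    ),
    "needle tracks": DepotSpec(
        shape_kind="track_set",
        center=(2200.0, 2200.0, 1200.0),
        size_params={
            "tracks": [
                {"start": (-700.0, 0.0, -700.0), "end": (-700.0, 0.0, 700.0),
                 "radius": 130.0},
                {"start": (700.0, 200.0, -700.0), "end": (700.0, 200.0, 600.0),
                 "radius": 120.0},
                {"start": (0.0, -600.0, -500.0), "end": (0.0, -600.0, 700.0),
                 "radius": 140.0},
            ]
        },
    ),
}

for name, depot in depots.items():
    phantom = make_phantom(depot, tissue, grid_spacing=20.0, seed=3)
    stack = simulate_blockface_stack(phantom, ImagingConfig(rng_seed=4))
    fluor = resample_stack_to_volume(stack, "fluorescence")
    refl = resample_stack_to_volume(stack, "reflection")
    seg = segment_fluorescence(fluor, build_tissue_mask(refl))
    rep = quant_report(seg)
    ext = ", ".join(f"{e:.0f}" for e in rep.shape.principal_extents_um)
    print(f"{name}:")
    print(f"  volume        : {rep.fluorescent_volume_ul:.3f} µL "
          f"(true {phantom.depot.true_volume_um3 / 1e9:.3f} µL)")
    print(f"  fragmentation : {rep.shape.fragmentation} component(s)")
    print(f"  extents (µm)  : {ext}")
    print(f"  sphericity    : {rep.shape.sphericity:.2f}")
    print(f"  max depth     : {rep.shape.max_depth_um:.0f} µm")
# The compact bolus shows one near-spherical component; the track set is
# fragmented, elongated (large leading extent) and far less spherical —
# the same contrast seen between injection techniques in real samples.
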