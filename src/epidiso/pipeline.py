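"""End-to-end orchestration: images in, isocenter shift out.

These helpers glue the module APIs together exactly the way the CLI does
(read -> Canny -> measure -> pair -> aggregate), so library users, the CLI
and the closed-loop simulation all share one code path.
"""

from __future__ import annotations

from dataclasses import replace

from .config import MachineConfig
from .dicom_io import PortalImage
from .measurement import JawMeasurement, detect_edges, measure
from .solver import IsocenterResult, aggregate, pair_measurements, plan_acquisition


def measure_images(
    images: list[PortalImage], config: MachineConfig | None = None
) -> list[JawMeasurement]:
    """Run edge detection and jaw/phantom measurement on every image."""
    config = config or MachineConfig(vendor=images[0].vendor if images else "varian")
    out: list[JawMeasurement] = []
    for img in images:
        edge_map = detect_edges(img, config.canny_for(img.view))
        out.extend(measure(img, edge_map, phantom=config.phantom, jaws=config.jaws))
    return out


def analyze_images(
    images: list[PortalImage],
    config: MachineConfig | None = None,
    strict: bool = True,
) -> IsocenterResult:
    """Full analysis of one session's portal images."""
    config = config or MachineConfig(vendor=images[0].vendor if images else "varian")
    measurements = measure_images(images, config)
    pairs = pair_measurements(measurements, strict=strict)
    result = aggregate(pairs, couch_signs=config.couch_signs)
    result.measurements = measurements
    return result


def closed_loop_residual(
    truth,
    vendor: str = "varian",
    mode: str = "full",
    config: MachineConfig | None = None,
    **render_kwargs,
):
    """Simulated end-to-end accuracy trial.

    Renders a session for ``truth``, computes the couch shift, applies it
    to the phantom offset (identity couch signs move the phantom by the
    reported shift), re-renders and re-analyses.  Returns
    ``(first_result, residual_result)``; the residual session's |S_r| is
    the accuracy figure of merit.
    """
    from .synthetic import render_session  # avoid import cycle at module load

    plan = plan_acquisition(vendor, mode)
    config = config or MachineConfig(
        vendor=vendor, **{k: v for k, v in render_kwargs.items() if k in
                          ("sad_mm", "sid_mm", "pixel_spacing_mm", "field_size_mm")}
    )
    first = analyze_images(render_session(truth, plan, **render_kwargs), config)
    shifted_offset = tuple(
        o + first.couch_shift_mm[d]
        for o, d in zip(truth.phantom_offset_mm, ("lateral", "longitudinal", "vertical"))
    )
    shifted_truth = replace(truth, phantom_offset_mm=shifted_offset, seed=truth.seed + 1)
    residual = analyze_images(render_session(shifted_truth, plan, **render_kwargs), config)
    return first, residual
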