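"""BCARS processing of a core-shell droplet cube.

Raw CARS spectra are converted to Raman-like spectra by Kramers-Kronig
phase retrieval against the nonresonant surroundings, the droplet is
segmented on the amide-I map, and concentric-ring spectra are compared.
A matured shell shows the narrow 1665 cm^-1 feature absent from the core.
"""

import numpy as np

from maturation.raman import (
    amide_map,
    compare_core_shell,
    retrieve_cube,
    ring_spectra,
    segment_rings,
)
from maturation.synth import CarsConfig, make_cars_cube

cube, truth = make_cars_cube(CarsConfig(seed=7))
raman = retrieve_cube(cube)
amap = amide_map(cube, raman=raman)
seg = segment_rings(amap, n_rings=5)
print(f"droplet: {seg.mask.sum()} px in 5 rings; "
      f"shell pixels in border ring: "
      f"{(seg.ring_index[truth['shell_mask']] == seg.border_index).mean():.0%}")

rings = ring_spectra(cube, seg, raman=raman)
report = compare_core_shell(rings)
print(f"border - internal difference peaks at "
      f"{report['peak_position']:.0f} cm^-1 "
      f"(height {report['height_1665']:.4f}, FWHM {report['fwhm_1665']:.0f} cm^-1)")
print(f"tyrosine 1618 cm^-1 difference height: {report['height_1618']:.4f}")

w = cube.wavenumber
core_mean = raman[truth["core_mask"]].mean(axis=0)
print(f"strongest core band: {w[np.argmax(core_mean)]:.0f} cm^-1 "
      "(broad amide I)")
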