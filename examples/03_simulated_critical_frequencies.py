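"""Simulated monomer and dimer critical frequencies on the four geometries.

Integrates the overdamped motion of a single bead (and of a rigid
two-bead dimer) on each array's travelling flux-density landscape and
bisects for the drive frequency at which phase locking is lost.  A single
calibration — scaling all frequencies so the circular-array monomer lands
on its measured 27 Hz — then gives the chip-to-chip comparison: triangles
are slowest, rectangles fastest, and only the small magnets (C, S, T)
separate dimers from monomers.  Runtime is about a minute.
"""

from nlmsim import BeadSpec, DimerSpec, ExternalFieldSpec, standard_array
from nlmsim.dynamics import PeriodicLandscapeTable, find_critical_frequency

ext = ExternalFieldSpec()
fc = {}
for code in "CSTR":
    array = standard_array(code)
    table = PeriodicLandscapeTable(array)
    fc[code] = (
        find_critical_frequency(BeadSpec(), array, ext, table=table),
        find_critical_frequency(DimerSpec(), array, ext, table=table),
    )

cal = 27.0 / fc["C"][0]  # single calibration on circle monomers
print("geometry   monomer f_c (Hz)   dimer f_c (Hz)   gap (Hz)   [calibrated]")
for code in "CSTR":
    m, d = (cal * v for v in fc[code])
    print(f"   {code}          {m:6.1f}            {d:6.1f}        {m - d:5.1f}")

print(
    "\nDimers slip earlier than monomers on C, S and T because part of their\n"
    "volume overhangs the magnet edge where the field contrast is weaker;\n"
    "on the tall rectangle both species see the same landscape and the gap\n"
    "closes — that array transports fast but cannot separate the species."
)
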