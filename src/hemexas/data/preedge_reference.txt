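# PLACEHOLDER Fe(III) pre-edge reference regions -- SYNTHETIC VALUES.
#
# Integrated pre-edge peak area vs area-weighted centroid regions for
# tetra-, penta- and hexa-coordinated Fe(III) compounds.  The boundaries
# below are NOT literature values: they are placeholder rectangles
# positioned so that the package's synthetic pre-edge presets fall in the
# expected classes, ordered by the physical trend (lower coordination ->
# larger pre-edge area from stronger p-d mixing).  Substitute measured
# reference-compound regions from the literature before classifying real
# data.
#
# columns: label  centroid_lo_eV  centroid_hi_eV  area_lo  area_hi
tetra   7112.30  7113.30  0.25  0.45
penta   7112.50  7113.30  0.10  0.22
hexa    7113.40  7114.30  0.06  0.20
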