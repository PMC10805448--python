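"""Regenerate the shipped data fixtures (run from the repository root).

Writes:
  src/wmnet/data/aal90_atlas.csv          - 90-region AAL table with lobe/class labels
  src/wmnet/data/aal90_coords_synthetic.csv - synthetic mirrored node coordinates
"""
import csv
import numpy as np

# (abbrev, name, lobe, class) in AAL pair order; odd index = left, even = right
PAIRS = [
    ("PreCG", "Precentral gyrus", "central", "primary"),
    ("SFGdor", "Superior frontal gyrus", "frontal", "association"),
    ("ORBsup", "Superior orbitofrontal gyrus", "frontal", "paralimbic"),
    ("MFG", "Middle frontal gyrus", "frontal", "association"),
    ("ORBmid", "Middle orbitofrontal gyrus", "frontal", "paralimbic"),
    ("IFGoperc", "Inferior frontal gyrus (opercular)", "frontal", "association"),
    ("IFGtriang", "Inferior frontal gyrus (triangular)", "frontal", "association"),
    ("ORBinf", "Inferior orbitofrontal gyrus", "frontal", "paralimbic"),
    ("ROL", "Rolandic operculum", "central", "primary"),
    ("SMA", "Supplementary motor area", "frontal", "association"),
    ("OLF", "Olfactory gyrus", "frontal", "paralimbic"),
    ("SFGmed", "Medial frontal gyrus", "frontal", "association"),
    ("ORBmed", "Medial orbitofrontal gyrus", "frontal", "paralimbic"),
    ("REC", "Rectus gyrus", "frontal", "paralimbic"),
    ("INS", "Insula", "insula", "paralimbic"),
    ("ACG", "Anterior cingulate gyrus", "limbic", "paralimbic"),
    ("MCG", "Middle cingulate gyrus", "limbic", "paralimbic"),
    ("PCG", "Posterior cingulate gyrus", "limbic", "paralimbic"),
    ("HIP", "Hippocampus", "limbic", "paralimbic"),
    ("PHG", "Parahippocampal gyrus", "limbic", "paralimbic"),
    ("AMYG", "Amygdala", "limbic", "paralimbic"),
    ("CAL", "Calcarine", "occipital", "primary"),
    ("CUN", "Cuneus", "occipital", "association"),
    ("LING", "Lingual gyrus", "occipital", "association"),
    ("SOG", "Superior occipital gyrus", "occipital", "association"),
    ("MOG", "Middle occipital gyrus", "occipital", "association"),
    ("IOG", "Inferior occipital gyrus", "occipital", "association"),
    ("FFG", "Fusiform gyrus", "temporal", "association"),
    ("PoCG", "Postcentral gyrus", "central", "primary"),
    ("SPG", "Superior parietal gyrus", "parietal", "association"),
    ("IPL", "Inferior parietal gyrus", "parietal", "association"),
    ("SMG", "Supramarginal gyrus", "parietal", "association"),
    ("ANG", "Angular gyrus", "parietal", "association"),
    ("PCUN", "Precuneus", "parietal", "association"),
    ("PCL", "Paracentral lobule", "central", "primary"),
    ("CAU", "Caudate nucleus", "subcortical", "subcortical"),
    ("PUT", "Lenticular nucleus, putamen", "subcortical", "subcortical"),
    ("PAL", "Lenticular nucleus, pallidum", "subcortical", "subcortical"),
    ("THA", "Thalamus", "subcortical", "subcortical"),
    ("HES", "Heschl gyrus", "temporal", "primary"),
    ("STG", "Superior temporal gyrus", "temporal", "association"),
    ("TPOsup", "Temporal pole: superior temporal pole", "temporal", "paralimbic"),
    ("TPOmid", "Temporal pole: middle temporal pole", "temporal", "paralimbic"),
    ("MTG", "Middle temporal gyrus", "temporal", "association"),
    ("ITG", "Inferior temporal gyrus", "temporal", "association"),
]

# synthetic lobe anchors (|x|, y, z) in mm, roughly MNI-like; regions within a lobe
# are spread along y/z so distances look anatomically plausible
ANCHORS = {
    "central":     (35.0, -10.0, 50.0),
    "frontal":     (25.0, 35.0, 25.0),
    "temporal":    (50.0, -20.0, -15.0),
    "parietal":    (30.0, -55.0, 45.0),
    "occipital":   (20.0, -80.0, 10.0),
    "limbic":      (10.0, -15.0, 20.0),
    "insula":      (38.0, 2.0, 2.0),
    "subcortical": (18.0, 2.0, 5.0),
}


def main():
    rng = np.random.default_rng(20230825)
    with open("src/wmnet/data/aal90_atlas.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "name", "abbreviation", "hemisphere", "lobe", "class"])
        for k, (ab, name, lobe, cls) in enumerate(PAIRS):
            w.writerow([2 * k + 1, name, f"{ab}_L", "L", lobe, cls])
            w.writerow([2 * k + 2, name, f"{ab}_R", "R", lobe, cls])

    # per-lobe sequential placement with mirrored jitter
    counters = {k: 0 for k in ANCHORS}
    rows = []
    for k, (ab, name, lobe, cls) in enumerate(PAIRS):
        ax, ay, az = ANCHORS[lobe]
        i = counters[lobe]
        counters[lobe] += 1
        dy, dz = rng.uniform(-6, 6, 2)
        x = ax + rng.uniform(-8, 8)
        y = ay + 9.0 * (i - 3) / 2.0 + dy
        z = az + 7.0 * ((i % 4) - 1.5) + dz
        rows.append([2 * k + 1, round(-x, 2), round(y, 2), round(z, 2)])
        rows.append([2 * k + 2, round(x, 2), round(y, 2), round(z, 2)])
    with open("src/wmnet/data/aal90_coords_synthetic.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "x", "y", "z"])
        w.writerows(rows)
    print("wrote fixtures")


if __name__ == "__main__":
    main()
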