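# Site -> island/coast assignment used for regional subset re-analysis.
# Vancouver Island east/west follows coastal geography (Strait of Georgia
# side vs outer coast); override via read_dataset(region_map=...).
M-PP: Moorea
M-Pa: Moorea
M-Th: Moorea
M-Fa: Moorea
M-Vn: Moorea
M-Vr: Moorea
M-Ti: Moorea
M-At: Moorea
M-Hu: Moorea
M-Ha: Moorea
M-Mh: Moorea
M-Te: Moorea
M-Ma: Moorea
M-EB: Moorea
M-Op: Moorea
M-Af: Moorea
V-CI: VancouverEast
V-Cr: VancouverEast
V-FB: VancouverEast
V-NB: VancouverEast
V-PI: VancouverEast
V-Ld: VancouverEast
V-Sd: VancouverEast
V-Vi: VancouverEast
V-Sk: VancouverWest
V-CB: VancouverWest
V-Bf: VancouverWest
V-PA: VancouverWest
V-SB: VancouverWest
V-LB: VancouverWest
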