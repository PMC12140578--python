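{
 "name": "mindboggle62",
 "scouts": [
  {
   "name": "caudalanteriorcingulate L",
   "hemisphere": "L",
   "lobe": "limbic"
  },
  {
   "name": "caudalanteriorcingulate R",
   "hemisphere": "R",
   "lobe": "limbic"
  },
  {
   "name": "caudalmiddlefrontal L",
   "hemisphere": "L",
   "lobe": "frontal"
  },
  {
   "name": "caudalmiddlefrontal R",
   "hemisphere": "R",
   "lobe": "frontal"
  },
  {
   "name": "cuneus L",
   "hemisphere": "L",
   "lobe": "occipital"
  },
  {
   "name": "cuneus R",
   "hemisphere": "R",
   "lobe": "occipital"
  },
  {
   "name": "entorhinal L",
   "hemisphere": "L",
   "lobe": "temporal"
  },
  {
   "name": "entorhinal R",
   "hemisphere": "R",
   "lobe": "temporal"
  },
  {
   "name": "fusiform L",
   "hemisphere": "L",
   "lobe": "temporal"
  },
  {
   "name": "fusiform R",
   "hemisphere": "R",
   "lobe": "temporal"
  },
  {
   "name": "inferiorparietal L",
   "hemisphere": "L",
   "lobe": "parietal"
  },
  {
   "name": "inferiorparietal R",
   "hemisphere": "R",
   "lobe": "parietal"
  },
  {
   "name": "inferiortemporal L",
   "hemisphere": "L",
   "lobe": "temporal"
  },
  {
   "name": "inferiortemporal R",
   "hemisphere": "R",
   "lobe": "temporal"
  },
  {
   "name": "insula L",
   "hemisphere": "L",
   "lobe": "insula"
  },
  {
   "name": "insula R",
   "hemisphere": "R",
   "lobe": "insula"
  },
  {
   "name": "isthmuscingulate L",
   "hemisphere": "L",
   "lobe": "limbic"
  },
  {
   "name": "isthmuscingulate R",
   "hemisphere": "R",
   "lobe": "limbic"
  },
  {
   "name": "lateraloccipital L",
   "hemisphere": "L",
   "lobe": "occipital"
  },
  {
   "name": "lateraloccipital R",
   "hemisphere": "R",
   "lobe": "occipital"
  },
  {
   "name": "lateralorbitofrontal L",
   "hemisphere": "L",
   "lobe": "frontal"
  },
  {
   "name": "lateralorbitofrontal R",
   "hemisphere": "R",
   "lobe": "frontal"
  },
  {
   "name": "lingual L",
   "hemisphere": "L",
   "lobe": "occipital"
  },
  {
   "name": "lingual R",
   "hemisphere": "R",
   "lobe": "occipital"
  },
  {
   "name": "medialorbitofrontal L",
   "hemisphere": "L",
   "lobe": "frontal"
  },
  {
   "name": "medialorbitofrontal R",
   "hemisphere": "R",
   "lobe": "frontal"
  },
  {
   "name": "middletemporal L",
   "hemisphere": "L",
   "lobe": "temporal"
  },
  {
   "name": "middletemporal R",
   "hemisphere": "R",
   "lobe": "temporal"
  },
  {
   "name": "paracentral L",
   "hemisphere": "L",
   "lobe": "frontal"
  },
  {
   "name": "paracentral R",
   "hemisphere": "R",
   "lobe": "frontal"
  },
  {
   "name": "parahippocampal L",
   "hemisphere": "L",
   "lobe": "temporal"
  },
  {
   "name": "parahippocampal R",
   "hemisphere": "R",
   "lobe": "temporal"
  },
  {
   "name": "parsopercularis L",
   "hemisphere": "L",
   "lobe": "frontal"
  },
  {
   "name": "parsopercularis R",
   "hemisphere": "R",
   "lobe": "frontal"
  },
  {
   "name": "parsorbitalis L",
   "hemisphere": "L",
   "lobe": "frontal"
  },
  {
   "name": "parsorbitalis R",
   "hemisphere": "R",
   "lobe": "frontal"
  },
  {
   "name": "parstriangularis L",
   "hemisphere": "L",
   "lobe": "frontal"
  },
  {
   "name": "parstriangularis R",
   "hemisphere": "R",
   "lobe": "frontal"
  },
  {
   "name": "pericalcarine L",
   "hemisphere": "L",
   "lobe": "occipital"
  },
  {
   "name": "pericalcarine R",
   "hemisphere": "R",
   "lobe": "occipital"
  },
  {
   "name": "postcentral L",
   "hemisphere": "L",
   "lobe": "parietal"
  },
  {
   "name": "postcentral R",
   "hemisphere": "R",
   "lobe": "parietal"
  },
  {
   "name": "posteriorcingulate L",
   "hemisphere": "L",
   "lobe": "limbic"
  },
  {
   "name": "posteriorcingulate R",
   "hemisphere": "R",
   "lobe": "limbic"
  },
  {
   "name": "precentral L",
   "hemisphere": "L",
   "lobe": "frontal"
  },
  {
   "name": "precentral R",
   "hemisphere": "R",
   "lobe": "frontal"
  },
  {
   "name": "precuneus L",
   "hemisphere": "L",
   "lobe": "parietal"
  },
  {
   "name": "precuneus R",
   "hemisphere": "R",
   "lobe": "parietal"
  },
  {
   "name": "rostralanteriorcingulate L",
   "hemisphere": "L",
   "lobe": "limbic"
  },
  {
   "name": "rostralanteriorcingulate R",
   "hemisphere": "R",
   "lobe": "limbic"
  },
  {
   "name": "rostralmiddlefrontal L",
   "hemisphere": "L",
   "lobe": "frontal"
  },
  {
   "name": "rostralmiddlefrontal R",
   "hemisphere": "R",
   "lobe": "frontal"
  },
  {
   "name": "superiorfrontal L",
   "hemisphere": "L",
   "lobe": "frontal"
  },
  {
   "name": "superiorfrontal R",
   "hemisphere": "R",
   "lobe": "frontal"
  },
  {
   "name": "superiorparietal L",
   "hemisphere": "L",
   "lobe": "parietal"
  },
  {
   "name": "superiorparietal R",
   "hemisphere": "R",
   "lobe": "parietal"
  },
  {
   "name": "superiortemporal L",
   "hemisphere": "L",
   "lobe": "temporal"
  },
  {
   "name": "superiortemporal R",
   "hemisphere": "R",
   "lobe": "temporal"
  },
  {
   "name": "supramarginal L",
   "hemisphere": "L",
   "lobe": "parietal"
  },
  {
   "name": "supramarginal R",
   "hemisphere": "R",
   "lobe": "parietal"
  },
  {
   "name": "transversetemporal L",
   "hemisphere": "L",
   "lobe": "temporal"
  },
  {
   "name": "transversetemporal R",
   "hemisphere": "R",
   "lobe": "temporal"
  }
 ],
 "region_sets": {
  "frontal_left": [
   "caudalmiddlefrontal L",
   "lateralorbitofrontal L",
   "medialorbitofrontal L",
   "paracentral L",
   "parsopercularis L",
   "parsorbitalis L",
   "parstriangularis L",
   "precentral L",
   "rostralmiddlefrontal L",
   "superiorfrontal L"
  ],
  "frontal_right": [
   "caudalmiddlefrontal R",
   "lateralorbitofrontal R",
   "medialorbitofrontal R",
   "paracentral R",
   "parsopercularis R",
   "parsorbitalis R",
   "parstriangularis R",
   "precentral R",
   "rostralmiddlefrontal R",
   "superiorfrontal R"
  ]
 }
}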