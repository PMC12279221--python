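{
  "version": "1.0",
  "description": "Default bilateral motor/prefrontal montage: 8 sources, 16 detectors, 30 channels at a nominal 30 mm source-detector separation, covering prefrontal cortex (PFC), premotor cortex (PMC), supplementary motor area (SMA) and primary motor cortex (M1) on both hemispheres. Optode positions are nominal 10-20-derived head coordinates in mm and are informational only; the channel->ROI table is a best-effort reading of the probe figure and can be overridden by loading a user JSON with the same schema.",
  "separation_mm": 30.0,
  "sources": {
    "S1": [-39, 52, 40],
    "S2": [-52, 24, 50],
    "S3": [-22, 8, 72],
    "S4": [-60, -8, 54],
    "S5": [39, 52, 40],
    "S6": [52, 24, 50],
    "S7": [22, 8, 72],
    "S8": [60, -8, 54]
  },
  "detectors": {
    "D1": [-54, 62, 26],
    "D2": [-24, 64, 46],
    "D3": [-46, 38, 52],
    "D4": [-36, 16, 64],
    "D5": [-62, 18, 40],
    "D6": [-48, -2, 62],
    "D7": [-12, -10, 76],
    "D8": [-58, -24, 48],
    "D9": [54, 62, 26],
    "D10": [24, 64, 46],
    "D11": [46, 38, 52],
    "D12": [36, 16, 64],
    "D13": [62, 18, 40],
    "D14": [48, -2, 62],
    "D15": [12, -10, 76],
    "D16": [58, -24, 48]
  },
  "channels": [
    ["S1", "D1"], ["S1", "D2"], ["S1", "D3"],
    ["S2", "D3"], ["S2", "D4"], ["S2", "D5"], ["S2", "D6"],
    ["S3", "D4"], ["S3", "D6"], ["S3", "D7"], ["S3", "D8"],
    ["S4", "D5"], ["S4", "D6"], ["S4", "D7"], ["S4", "D8"],
    ["S5", "D9"], ["S5", "D10"], ["S5", "D11"],
    ["S6", "D11"], ["S6", "D12"], ["S6", "D13"], ["S6", "D14"],
    ["S7", "D12"], ["S7", "D14"], ["S7", "D15"], ["S7", "D16"],
    ["S8", "D13"], ["S8", "D14"], ["S8", "D15"], ["S8", "D16"]
  ],
  "roi_map": {
    "S1-D1": "lPFC", "S1-D2": "lPFC", "S1-D3": "lPFC",
    "S2-D3": "lPMC", "S2-D4": "lPMC", "S2-D5": "lPMC", "S2-D6": "lPMC",
    "S3-D4": "lSMA", "S3-D6": "lSMA", "S3-D7": "lSMA", "S3-D8": "lSMA",
    "S4-D5": "lM1", "S4-D6": "lM1", "S4-D7": "lM1", "S4-D8": "lM1",
    "S5-D9": "rPFC", "S5-D10": "rPFC", "S5-D11": "rPFC",
    "S6-D11": "rPMC", "S6-D12": "rPMC", "S6-D13": "rPMC", "S6-D14": "rPMC",
    "S7-D12": "rSMA", "S7-D14": "rSMA", "S7-D15": "rSMA", "S7-D16": "rSMA",
    "S8-D13": "rM1", "S8-D14": "rM1", "S8-D15": "rM1", "S8-D16": "rM1"
  }
}
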