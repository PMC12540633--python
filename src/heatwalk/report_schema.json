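{
 "type": "object",
 "required": ["config", "campaign", "hotspots"],
 "properties": {
  "config": {
   "type": "object",
   "required": ["fraction", "cluster_gap_m", "min_cluster_points", "intersect_buffer_m", "snap_max_m", "wind_10m", "seed"],
   "properties": {
    "fraction": {"type": "number"},
    "cluster_gap_m": {"type": "number"},
    "min_cluster_points": {"type": "integer"},
    "intersect_buffer_m": {"type": "number"},
    "snap_max_m": {"type": "number"},
    "wind_10m": {"type": "number"},
    "seed": {"type": ["integer", "null"]}
   }
  },
  "campaign": {
   "type": "object",
   "required": ["n_laps", "n_excluded", "utci_ranges"],
   "properties": {
    "n_laps": {"type": "integer"},
    "n_excluded": {"type": "integer"},
    "utci_ranges": {"type": "array"}
   }
  },
  "hotspots": {
   "type": "object",
   "required": ["hot_zones", "cold_zones"],
   "properties": {
    "hot_zones": {"type": "array"},
    "cold_zones": {"type": "array"}
   }
  },
  "survey": {
   "type": ["object", "null"],
   "properties": {
    "r_tsv_utci": {"type": ["number", "null"]},
    "r_tcv_utci": {"type": ["number", "null"]},
    "neutral_interval": {"type": ["array", "null"]},
    "discrepancy_stops": {"type": "array"}
   }
  }
 }
}
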