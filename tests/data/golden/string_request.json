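{
  "annotation_source": "GO-BP",
  "endpoint": "https://string-db.org/api/json/network",
  "method": "POST",
  "params": {
    "add_white_nodes": 0,
    "caller_identity": "lipidindex",
    "identifiers": "ACADM\rACAT1\rACSL1\rACSL4\rAGPAT2\rAGPS\rALOX15\rCPT1A\rCerS1\rCerS2\rDGAT1\rDGAT2\rFAR1\rFASN\rGNPAT\rGPAM\rGPCPD1\rGPX4\rHEXA\rHEXB\rLCAT\rLIPE\rLPL\rLTA4H\rPDK1\rPLA2\rPLA2G4A\rPLA2G6\rPLD1\rPNPLA2\rPTGS1\rSCD\rSMS1\rSMS2\rSPTLC1\rST3GAL5\rTMEM189",
    "network_type": "full",
    "required_score": 400,
    "species": 9606
  }
}
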