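{
  "_comment": "Coarse polygonal approximation of favored/allowed Ramachandran density contours per residue class. Vertices are (phi, psi) in degrees. Classification: favored if inside any favored polygon, else allowed if inside any allowed polygon, else outlier. Polygons are a compact stand-in for the published high-resolution density grids.",
  "general": {
    "favored": [
      [[-180, 80], [-60, 80], [-60, 180], [-180, 180]],
      [[-180, 170], [-180, 180], [-60, 180], [-60, 170]],
      [[-160, -60], [-45, -60], [-45, 0], [-160, 0]],
      [[50, 20], [70, 20], [70, 60], [50, 60]]
    ],
    "allowed": [
      [[-180, 60], [-45, 60], [-45, 180], [-180, 180]],
      [[-180, -180], [-45, -180], [-45, -150], [-180, -150]],
      [[-180, -80], [-40, -80], [-40, 20], [-180, 20]],
      [[45, 15], [80, 15], [80, 70], [45, 70]]
    ]
  },
  "glycine": {
    "favored": [
      [[-160, -60], [-45, -60], [-45, 40], [-160, 40]],
      [[45, -40], [160, -40], [160, 60], [45, 60]],
      [[-180, 140], [-40, 140], [-40, 180], [-180, 180]],
      [[40, -180], [180, -180], [180, -140], [40, -140]]
    ],
    "allowed": [
      [[-180, -80], [-30, -80], [-30, 60], [-180, 60]],
      [[30, -60], [180, -60], [180, 80], [30, 80]],
      [[-180, 100], [-30, 100], [-30, 180], [-180, 180]],
      [[30, -180], [180, -180], [180, -100], [30, -100]],
      [[-180, -180], [-30, -180], [-30, -140], [-180, -140]],
      [[30, 140], [180, 140], [180, 180], [30, 180]]
    ]
  },
  "proline": {
    "favored": [
      [[-95, -45], [-45, -45], [-45, -10], [-95, -10]],
      [[-95, 100], [-45, 100], [-45, 180], [-95, 180]]
    ],
    "allowed": [
      [[-110, -60], [-40, -60], [-40, 30], [-110, 30]],
      [[-110, 80], [-40, 80], [-40, 180], [-110, 180]],
      [[-110, -180], [-40, -180], [-40, -150], [-110, -150]]
    ]
  },
  "pre-proline": {
    "favored": [
      [[-180, 80], [-60, 80], [-60, 180], [-180, 180]],
      [[-160, -60], [-45, -60], [-45, 0], [-160, 0]]
    ],
    "allowed": [
      [[-180, 60], [-45, 60], [-45, 180], [-180, 180]],
      [[-180, -180], [-45, -180], [-45, -150], [-180, -150]],
      [[-180, -80], [-40, -80], [-40, 20], [-180, 20]],
      [[-135, 50], [-50, 50], [-50, 100], [-135, 100]]
    ]
  }
}
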