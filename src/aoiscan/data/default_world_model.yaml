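# Schematic planar layout of the ten cockpit AOIs used throughout the
# package.  Coordinates are millimetres on a flattened instrument-panel
# plane (x grows to the right, y grows upward, origin at the lower-left
# corner of the primary flight display column).  The primary flight
# display sub-regions (ids 1-5) are clustered, the navigation display and
# its distance read-out zone are adjacent, and the windshield sits above
# the glareshield.  Only relative geometry matters: every metric except
# the coefficient K amplitudes is geometry-free.
units: mm
regions:
  - id: 1
    label: ATT        # attitude indicator (PFD centre)
    rect: [100, 140, 180, 280]
  - id: 2
    label: SPD        # speed tape (PFD left)
    rect: [40, 140, 90, 280]
  - id: 3
    label: VS         # vertical-speed tape (PFD right)
    rect: [190, 140, 240, 280]
  - id: 4
    label: FMA        # flight-mode annunciator (PFD top strip)
    rect: [40, 280, 240, 320]
  - id: 5
    label: HDG        # heading tape (PFD bottom strip)
    rect: [40, 80, 240, 130]
  - id: 6
    label: ND         # navigation display
    rect: [280, 140, 480, 320]
  - id: 7
    label: NDz        # distance read-out zone of the ND
    rect: [280, 80, 480, 130]
  - id: 8
    label: FCU        # flight control unit (glareshield)
    rect: [200, 340, 400, 390]
  - id: 9
    label: ECAM       # engine / aircraft monitoring display
    rect: [500, 80, 700, 320]
  - id: 10
    label: OTW        # out of the window
    rect: [0, 400, 600, 700]
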