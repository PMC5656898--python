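<!--
  Document type definition for the .top topology interchange format.

  A Topology stores the complete quantum-chemical-topology analysis of a
  scalar field: source metadata, nuclei, classified critical points and
  the gradient vector field (molecular graph, rings, cages, surfaces,
  basins, envelopes) built from gradient paths.

  Conventions:
    * all indices (Nucleus/CriticalPoint/AilRef/RingRef and every
      cp_start/cp_end/bcp/rcp/ccp/nacp attribute) are 0-based;
    * coordinates are in bohr; the Topology "unit" attribute is
      mandatory and must equal "bohr" (readers reject other values
      rather than silently converting);
    * scalar function names (Scalar "name") are an open vocabulary;
      "rho" denotes the electron density in atomic units;
    * a GradientPath truncated at the density floor carries
      terminus="infinity" and omits cp_end;
    * numeric attribute values are serialized with 12 significant digits.
-->
<!ELEMENT Topology (SourceInformation, Nucleus*, CriticalPoint*, GradientVectorField)>
<!ATTLIST Topology unit CDATA #REQUIRED>

<!ELEMENT SourceInformation EMPTY>
<!ATTLIST SourceInformation
  qm_method CDATA ""
  basis_set CDATA ""
  wavefunction_program CDATA ""
  qct_program CDATA "">

<!ELEMENT PositionVector EMPTY>
<!ATTLIST PositionVector x CDATA #REQUIRED y CDATA #REQUIRED z CDATA #REQUIRED>

<!ELEMENT Nucleus (PositionVector)>
<!ATTLIST Nucleus index CDATA #REQUIRED element CDATA #REQUIRED>

<!ELEMENT Point (PositionVector, Scalar*)>
<!ELEMENT Scalar EMPTY>
<!ATTLIST Scalar name CDATA #REQUIRED value CDATA #REQUIRED>

<!ELEMENT CriticalPoint (Point, Eigenvalues?, Eigenvectors?)>
<!ATTLIST CriticalPoint index CDATA #REQUIRED rank CDATA #REQUIRED signature CDATA #REQUIRED>
<!ELEMENT Eigenvalues EMPTY>
<!ATTLIST Eigenvalues l1 CDATA #REQUIRED l2 CDATA #REQUIRED l3 CDATA #REQUIRED>
<!ELEMENT Eigenvectors (PositionVector, PositionVector, PositionVector)>

<!ELEMENT GradientVectorField (MolecularGraph?, Ring*, Cage*, AtomicSurface*, RingSurface*, AtomicBasin*, Envelope*)>

<!ELEMENT GradientPath (Point, Point+)>
<!ATTLIST GradientPath cp_start CDATA #REQUIRED cp_end CDATA #IMPLIED terminus CDATA #IMPLIED>

<!ELEMENT MolecularGraph (AtomicInteractionLine*)>
<!ELEMENT AtomicInteractionLine (GradientPath, GradientPath)>
<!ATTLIST AtomicInteractionLine bcp CDATA #REQUIRED>

<!ELEMENT Ring (AilRef, AilRef, AilRef+)>
<!ATTLIST Ring rcp CDATA #REQUIRED>
<!ELEMENT AilRef EMPTY>
<!ATTLIST AilRef index CDATA #REQUIRED>

<!ELEMENT Cage (RingRef, RingRef+)>
<!ATTLIST Cage ccp CDATA #REQUIRED>
<!ELEMENT RingRef EMPTY>
<!ATTLIST RingRef index CDATA #REQUIRED>

<!ELEMENT AtomicSurface (InteratomicSurface*)>
<!ATTLIST AtomicSurface nacp CDATA #REQUIRED>
<!ELEMENT InteratomicSurface (GradientPath*, Triangulation?)>
<!ATTLIST InteratomicSurface bcp CDATA #REQUIRED>

<!ELEMENT RingSurface (GradientPath*)>
<!ATTLIST RingSurface rcp CDATA #REQUIRED>

<!ELEMENT AtomicBasin (GradientPath*)>
<!ATTLIST AtomicBasin nacp CDATA #REQUIRED>

<!ELEMENT Envelope (Point*, Triangulation)>
<!ATTLIST Envelope nacp CDATA #REQUIRED isovalue CDATA #REQUIRED>

<!ELEMENT Triangulation (Vertex*, Edge*, Face*)>
<!ELEMENT Vertex (PositionVector)>
<!ELEMENT Edge EMPTY>
<!ATTLIST Edge a CDATA #REQUIRED b CDATA #REQUIRED>
<!ELEMENT Face EMPTY>
<!ATTLIST Face a CDATA #REQUIRED b CDATA #REQUIRED c CDATA #REQUIRED>
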