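<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:simpleType name="floatOrNan">
    <xs:restriction base="xs:string">
      <xs:pattern value="-?[0-9]+(\.[0-9]+)?([eE][+-]?[0-9]+)?|nan|inf|-inf"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="boolInt">
    <xs:restriction base="xs:integer">
      <xs:minInclusive value="0"/>
      <xs:maxInclusive value="1"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="sizeOrOverflow">
    <xs:restriction base="xs:string">
      <xs:pattern value="[0-9]+|overflow"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="alnqc_report">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="sample" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="provenance">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="entry" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="key" type="xs:string" use="required"/>
                        <xs:attribute name="value" type="xs:string" use="required"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="summary">
                <xs:complexType>
                  <xs:attribute name="quality_mse" type="floatOrNan" use="required"/>
                  <xs:attribute name="gc_bias_score" type="floatOrNan" use="required"/>
                  <xs:attribute name="mean_depth" type="floatOrNan" use="required"/>
                  <xs:attribute name="mapped_fraction" type="floatOrNan" use="required"/>
                  <xs:attribute name="duplicate_fraction" type="floatOrNan" use="required"/>
                  <xs:attribute name="paired_fraction" type="floatOrNan" use="required"/>
                  <xs:attribute name="total_aligned_bases" type="xs:nonNegativeInteger" use="required"/>
                  <xs:attribute name="records_seen" type="xs:nonNegativeInteger" use="required"/>
                  <xs:attribute name="analysis_span" type="xs:positiveInteger" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="quality_concordance">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="bin" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="reported_q" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="n_matches" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="n_mismatches" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="n_bases" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="empirical_q" type="floatOrNan" use="required"/>
                        <xs:attribute name="censored" type="boolInt" use="required"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="cycles">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="cycle" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="index" type="xs:positiveInteger" use="required"/>
                        <xs:attribute name="n_bases" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="n_matches" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="n_mismatches" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="empirical_q" type="floatOrNan" use="required"/>
                        <xs:attribute name="censored" type="boolInt" use="required"/>
                        <xs:attribute name="mean_reported_q" type="floatOrNan" use="required"/>
                        <xs:attribute name="frac_A" type="floatOrNan" use="required"/>
                        <xs:attribute name="frac_C" type="floatOrNan" use="required"/>
                        <xs:attribute name="frac_G" type="floatOrNan" use="required"/>
                        <xs:attribute name="frac_T" type="floatOrNan" use="required"/>
                        <xs:attribute name="frac_N" type="floatOrNan" use="required"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="gc_bias">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="bin" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="gc_bin" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="n_windows" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="weight" type="floatOrNan" use="required"/>
                        <xs:attribute name="mean_depth" type="floatOrNan" use="required"/>
                        <xs:attribute name="normalized_depth" type="floatOrNan" use="required"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="expected_depth" type="floatOrNan"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="insert_sizes">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="group" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="point" minOccurs="0" maxOccurs="unbounded">
                            <xs:complexType>
                              <xs:attribute name="size" type="sizeOrOverflow" use="required"/>
                              <xs:attribute name="count" type="xs:positiveInteger" use="required"/>
                            </xs:complexType>
                          </xs:element>
                        </xs:sequence>
                        <xs:attribute name="id" type="xs:string" use="required"/>
                        <xs:attribute name="n_pairs" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="mode" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="mean" type="floatOrNan" use="required"/>
                        <xs:attribute name="median" type="floatOrNan" use="required"/>
                        <xs:attribute name="sd" type="floatOrNan" use="required"/>
                        <xs:attribute name="overflow_fraction" type="floatOrNan" use="required"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="label" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
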