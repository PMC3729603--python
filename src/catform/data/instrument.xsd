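<?xml version="1.0" encoding="UTF-8"?>
<!-- Canonical-form schema for instrument definition documents.
     This is the dialect of record: element and attribute names follow the
     running vocabulary of the instrument model (instrument, instrumentPolicies,
     instructions, instructionText, practiceItems, items, item@id, item@number,
     description, media, scoringCategory, scoring, categories, category@id,
     responses, response@id, label, mappingFunction, scoreComputation,
     lookupTable, scoringFunction, catTree).  The sequence order here is the
     canonical serialization order; the parser itself accepts any child order. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:complexType name="localizedTextType" mixed="true">
    <xs:attribute name="lang" type="xs:string" use="optional"/>
  </xs:complexType>

  <xs:complexType name="itemType">
    <xs:sequence>
      <xs:element name="description" type="localizedTextType" maxOccurs="unbounded"/>
      <xs:element name="media" type="xs:string" minOccurs="0"/>
      <xs:element name="scoringCategory" type="xs:string"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:string" use="required"/>
    <xs:attribute name="number" type="xs:nonNegativeInteger" use="required"/>
  </xs:complexType>

  <xs:complexType name="itemListType">
    <xs:sequence>
      <xs:element name="item" type="itemType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="responseType">
    <xs:sequence>
      <xs:element name="label" type="localizedTextType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:string" use="required"/>
    <xs:attribute name="label" type="xs:string" use="optional"/>
  </xs:complexType>

  <xs:complexType name="categoryType">
    <xs:sequence>
      <xs:element name="responses">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="response" type="responseType" maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="mappingFunction" type="xs:string" minOccurs="0"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:element name="instrument">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="instrumentPolicies" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="policy" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="key" type="xs:string" use="required"/>
                  <xs:attribute name="value" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="instructions" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="instructionText" type="localizedTextType" maxOccurs="unbounded"/>
              <xs:element name="practiceItems" type="itemListType" minOccurs="0"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="items" type="itemListType"/>
        <xs:element name="scoring">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="categories">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="category" type="categoryType" minOccurs="0" maxOccurs="unbounded"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="scoreComputation" minOccurs="0">
                <xs:complexType>
                  <xs:choice>
                    <xs:element name="lookupTable" type="xs:string"/>
                    <xs:element name="scoringFunction" type="xs:string"/>
                    <xs:element name="catTree" type="xs:string"/>
                  </xs:choice>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>
</xs:schema>
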